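import pandas as pd
import pytest

from trnapath.evaluation import LOOEvaluator
from trnapath.scoring import ScoringModel
from trnapath.simulate import FixtureSpec, make_fixture_set

#: Canonical cloverleaf element lengths used by hand-built test genes.
CANONICAL_STEMS = {"acceptor": 7, "d": 4, "anticodon": 5, "t": 5}


def manual_annotation(name, strand, start, *, d_loop=7, var_loop=5, t_loop=7, ac_loop=7):
    """Annotation rows for one hand-built cloverleaf; returns (rows, length)."""
    lengths = [
        ("acceptor_stem_5p", 7),
        ("d_stem_5p", 4),
        ("d_loop", d_loop),
        ("d_stem_3p", 4),
        ("anticodon_stem_5p", 5),
        ("anticodon_loop", ac_loop),
        ("anticodon_stem_3p", 5),
        ("variable_loop", var_loop),
        ("t_stem_5p", 5),
        ("t_loop", t_loop),
        ("t_stem_3p", 5),
        ("acceptor_stem_3p", 7),
        ("discriminator", 1),
    ]
    total = sum(length for _, length in lengths)
    rows = []
    if strand == "+":
        cursor = start
        for kind, length in lengths:
            rows.append(
                {"gene": name, "strand": strand, "start": cursor,
                 "end": cursor + length - 1, "element": kind}
            )
            cursor += length
    else:
        cursor = start + total - 1  # tRNA 5' end sits at the high coordinate
        for kind, length in lengths:
            rows.append(
                {"gene": name, "strand": strand, "start": cursor - length + 1,
                 "end": cursor, "element": kind}
            )
            cursor -= length
    return rows, total


def annotation_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "strand", "start", "end", "element"])


@pytest.fixture(scope="session")
def planted_fixture():
    """Default study conditions: 22 genes, 38 pathogenic / 651 benign, effect 0.9."""
    return make_fixture_set(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def null_fixture():
    return make_fixture_set(FixtureSpec(seed=1, effect_strength=0.0))


@pytest.fixture(scope="session")
def planted_evaluator(planted_fixture):
    fx = planted_fixture
    return LOOEvaluator(fx.genes, fx.evidence, fx.conservation, fx.labeled)


@pytest.fixture(scope="session")
def small_fixture():
    return make_fixture_set(
        FixtureSpec(n_genes=4, n_benign=40, n_pathogenic=8, seed=11)
    )


@pytest.fixture(scope="session")
def small_model(small_fixture):
    fx = small_fixture
    return ScoringModel(fx.genes, fx.evidence, fx.conservation)
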