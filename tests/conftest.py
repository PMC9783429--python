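import numpy as np
import pytest

from sacontrast.datamodel import transform_response
from sacontrast.simulate import SimulationConfig, analysis_model, generate_dataset


def make_experiment(**kw):
    """Generate a synthetic experiment plus its transformed table and model."""
    cfg = SimulationConfig(**kw)
    spec = analysis_model(cfg)
    table = transform_response(generate_dataset(cfg), spec.trait_spec)
    return table, spec, cfg


@pytest.fixture
def tiny_experiment():
    """72-record normal-family experiment (small enough for brute force)."""
    return make_experiment(pops_per_env=(2, 2, 2), units_per_pop_phase=2,
                           family="normal", seed=42)


@pytest.fixture
def study_experiment():
    """Study-like unbalanced layout (9/3/13 populations, 1200 records)."""
    return make_experiment(seed=7)


@pytest.fixture
def toy_csv(tmp_path):
    """Hand-written 4-row observation file: 1 population, 2 test envs."""
    p = tmp_path / "toy.csv"
    p.write_text(
        "population,origin,test,phase,unit,eggs\n"
        "P1,cherry,cherry,field,a1,10\n"
        "P1,cherry,strawberry,field,a1,4\n"
        "P1,cherry,cherry,common,a2,12\n"
        "P1,cherry,strawberry,common,a2,6\n"
    )
    return p


def sequential_ss_oracle(blocks, y):
    """Brute-force Type I SS: refit nested models, take RSS differences.

    Independent of the package's projection-based fit: each step solves a
    fresh least-squares problem on the accumulated raw columns.
    """
    y = np.asarray(y, float)
    parts = []
    prev_rss = float(y @ y)
    ss, df = {}, {}
    prev_rank = 0
    for name, B in blocks:
        parts.append(B if B.ndim == 2 else B[:, None])
        X = np.hstack(parts)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss = float(r @ r)
        rank = np.linalg.matrix_rank(X)
        ss[name] = prev_rss - rss
        df[name] = rank - prev_rank
        prev_rss, prev_rank = rss, rank
    return ss, df, prev_rss
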