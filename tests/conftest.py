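"""Shared fixtures: the toy model, cobra translations, and LP oracle helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from diatomgem.fba import SimulationConstraints
from diatomgem.synthetic import DEFAULT_ATPM, DEFAULT_GROWTH_RATE, build_toy_photoautotroph

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    """The deterministic toy photoautotroph and its manifest."""
    return build_toy_photoautotroph()


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def manifest(toy):
    return toy[1]


@pytest.fixture()
def default_constraints():
    return SimulationConstraints(growth=DEFAULT_GROWTH_RATE, atpm=DEFAULT_ATPM)


@pytest.fixture(scope="session")
def cobra_toy(toy_model, tmp_path_factory):
    """The toy model translated through SBML into cobrapy (GLPK solver)."""
    cobra = pytest.importorskip("cobra")
    from diatomgem.core import write_model

    path = tmp_path_factory.mktemp("sbml") / "toy.xml"
    write_model(toy_model, path)
    model = cobra.io.read_sbml_model(str(path))
    model.solver = "glpk_exact"  # plain glpk accepts small row violations here
    return model


def enumerate_split_bfs(S, lb, ub, tol=1e-9):
    """Minimal Σ|v| by brute-force basic-feasible-solution enumeration.

    The LP is put in the same forward/reverse split form used by pFBA
    (variables z = [p, q] ≥ 0, A z = 0, box bounds) and every basic feasible
    solution is enumerated: each basis is a column subset of size rank(A),
    with all nonbasic variables pinned to one of their bounds.  Exponential,
    usable only for fixtures with a handful of reactions — which is the point
    of an independent oracle.
    """
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    A = np.hstack([S, -S])
    lo = np.concatenate([np.maximum(lb, 0.0), np.maximum(-ub, 0.0)])
    hi = np.concatenate([np.maximum(ub, 0.0), np.maximum(-lb, 0.0)])
    r = np.linalg.matrix_rank(A) if A.size else 0
    N = 2 * n
    best = None
    best_v = None
    for basis in itertools.combinations(range(N), r):
        B = A[:, basis]
        if np.linalg.matrix_rank(B) < r:
            continue
        nonbasic = [j for j in range(N) if j not in basis]
        finite_choices = []
        for j in nonbasic:
            opts = []
            if np.isfinite(lo[j]):
                opts.append(lo[j])
            if np.isfinite(hi[j]) and hi[j] != lo[j]:
                opts.append(hi[j])
            if not opts:
                opts = [0.0]
            finite_choices.append(opts)
        for assignment in itertools.product(*finite_choices):
            z = np.zeros(N)
            z[list(nonbasic)] = assignment
            rhs = -A[:, nonbasic] @ z[list(nonbasic)]
            sol, residual, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            if np.linalg.norm(B @ sol - rhs) > 1e-7:
                continue
            z[list(basis)] = sol
            if np.any(z < lo - tol) or np.any(z > hi + tol):
                continue
            total = float(z.sum())
            if best is None or total < best - tol:
                best = total
                best_v = z[:n] - z[n:]
    return best, best_v
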