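"""Shared helpers for the test suite."""

import numpy as np

from ordstar.model import MRF, ModelSpec, Parametric, _build_blocks, _FitState, _inner_loop, _score_fisher


def edf_at_tau2(data, truth, tau2):
    """Effective df of an MRF block at a fixed variance, computed from
    an explicitly assembled dense system (independent of the fitter's
    bookkeeping).  Returns (edf, p, nullspace_dim)."""
    spec = ModelSpec(terms=[Parametric(["urban"]), MRF()])
    X_par, names, blocks = _build_blocks(data, spec, truth.graph)
    y = data.df["level"].to_numpy(int)
    state = _FitState(X_par, names, blocks, y, "probit")
    state.tau2 = [tau2]
    Sf = np.zeros((state.P + 2, state.P + 2))
    Sf[2:, 2:] = state.penalty_matrix()
    _inner_loop(state, Sf, 40)
    _, F = _score_fisher(state)
    H = np.linalg.inv(F + Sf)
    sl = state.slices[0]
    edf = float(np.einsum("ij,ji->i", H, F)[2 + sl.start:2 + sl.stop].sum())
    return edf, blocks[0].p, blocks[0].nullspace_dim
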