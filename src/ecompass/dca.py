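"""Direct coupling analysis over the scored columns of one alignment.

Pipeline: :func:`compute_weights` (identity-based sequence reweighting)
-> :func:`fit_potts` (L2-regularised pseudo-likelihood maximisation of a
21-state Potts model) -> :func:`frobenius_apc` (zero-sum gauge, Frobenius
norms over the 20 amino-acid states, average product correction).  The
result is a symmetric matrix of direct-coupling (DC) scores over scored
column pairs; only the *ordering* of these scores is consumed downstream.

Precomputed score matrices from external DCA tools can be loaded with
:func:`import_scores` instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .alphabet import GAP_STATE, N_AA, N_STATES
from .errors import ConfigError, DataError
from .msa_io import Msa

logger = logging.getLogger(__name__)


@dataclass
class SequenceWeights:
    """Per-record weights 1/(neighbourhood size) and their sum Meff."""

    weights: np.ndarray
    threshold: float

    @property
    def meff(self) -> float:
        return float(self.weights.sum())


@dataclass
class PottsModel:
    """Fields and pairwise couplings over the scored columns.

    ``couplings[k]`` is the 21x21 block for the k-th column pair in
    row-major upper-triangle order; ``coupling_block(i, j)`` returns the
    orientation-consistent block for any i != j.
    """

    n_cols: int
    fields: np.ndarray  # (L, 21)
    couplings: np.ndarray  # (L*(L-1)/2, 21, 21)
    metadata: dict = field(default_factory=dict)

    n_states: int = N_STATES

    def _pair_index(self, i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        L = self.n_cols
        return i * (2 * L - i - 1) // 2 + (j - i - 1)

    def coupling_block(self, i: int, j: int) -> np.ndarray:
        block = self.couplings[self._pair_index(i, j)]
        return block if i < j else block.T


@dataclass
class CouplingScores:
    """Symmetric DC-score matrix (APC-corrected Frobenius norms)."""

    scores: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_cols(self) -> int:
        return self.scores.shape[0]


# ---------------------------------------------------------------------------
# reweighting


def compute_weights(msa: Msa, threshold: float = 0.8) -> SequenceWeights:
    """Down-weight records by their number of near-identical neighbours.

    Identity between two records is the fraction of scored columns at which
    they carry the same residue; positions where either has a null count as
    mismatches and the denominator is the number of scored columns.  A
    record's weight is 1 over the number of records (itself included) with
    identity >= ``threshold``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ConfigError(f"reweighting threshold {threshold} outside (0, 1]")
    states = msa.identity_states(scored_only=True)
    n, width = states.shape
    if width == 0:
        raise DataError("no scored columns")
    # nulls are -1 and never match, so equality alone implements the rule
    neighbours = np.zeros(n, dtype=np.int64)
    chunk = max(1, int(2e7) // max(1, n * width))
    for start in range(0, n, chunk):
        block = states[start : start + chunk]
        ident = (block[:, None, :] == states[None, :, :]).sum(axis=2) / width
        neighbours[start : start + chunk] = (ident >= threshold).sum(axis=1)
    # a record's neighbourhood includes itself by definition, even when its
    # null content drags its self-identity below the threshold
    self_ident = (states >= 0).mean(axis=1)
    neighbours += self_ident < threshold
    return SequenceWeights(1.0 / neighbours, threshold)


# ---------------------------------------------------------------------------
# pseudo-likelihood fit


def _encode_potts(msa: Msa) -> np.ndarray:
    states = msa.identity_states(scored_only=True).astype(np.int64)
    states[states < 0] = GAP_STATE
    return states


def pseudolikelihood_objective(
    msa: Msa,
    weights: SequenceWeights,
    reg_strength: float = 0.2,
    reg_field: float = 0.01,
    dtype=np.float64,
):
    """The regularised negative pseudo-log-likelihood and its gradient.

    Returns ``(objective, n_parameters)`` where ``objective(x)`` yields
    ``(f, grad)`` over the flat parameter vector ``[fields, couplings]``.
    Exposed separately so the gradient can be checked against finite
    differences.
    """
    X = _encode_potts(msa)
    n, L = X.shape
    if L < 2:
        raise DataError("need at least 2 scored columns to fit couplings")
    q = N_STATES
    w = np.asarray(weights.weights, dtype=np.float64)
    if w.shape != (n,):
        raise DataError("weights do not match the number of records")
    tri_i, tri_j = np.triu_indices(L, k=1)
    n_pairs = len(tri_i)
    lam_h = float(reg_field)
    lam_e = float(reg_strength) * (L - 1)

    Xoh = np.zeros((n, L * q), dtype=dtype)
    Xoh[np.arange(n)[:, None], np.arange(L) * q + X] = 1.0
    wd = w.astype(dtype)[:, None, None]
    row_idx = np.arange(n)[:, None]
    col_idx = np.arange(L)[None, :]

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        h = x[: L * q].reshape(L, q)
        Jp = x[L * q :].reshape(n_pairs, q, q)
        W = np.zeros((L, q, L, q), dtype=dtype)
        W[tri_i, :, tri_j, :] = Jp
        W[tri_j, :, tri_i, :] = np.transpose(Jp, (0, 2, 1))
        Z = (Xoh @ W.reshape(L * q, L * q)).reshape(n, L, q)
        Z += h.astype(dtype)
        Zmax = Z.max(axis=2, keepdims=True)
        E = np.exp(Z - Zmax)
        S = E.sum(axis=2)
        lse = np.log(S) + Zmax[:, :, 0]
        Ztrue = np.take_along_axis(Z, X[:, :, None], axis=2)[:, :, 0]
        nll = float((w * (lse - Ztrue).sum(axis=1, dtype=np.float64)).sum())
        P = E / S[:, :, None]
        P[row_idx, col_idx, X] -= 1.0
        P *= wd
        gh = P.sum(axis=0, dtype=np.float64)
        G = (Xoh.T @ P.reshape(n, L * q)).astype(np.float64)
        G = G.reshape(L, q, L, q)
        gJ = G[tri_i, :, tri_j, :] + np.transpose(
            G[tri_j, :, tri_i, :], (0, 2, 1)
        )
        f = nll + lam_h * float((h**2).sum()) + lam_e * float((Jp**2).sum())
        gh = gh + 2.0 * lam_h * h
        gJ = gJ + 2.0 * lam_e * Jp
        return f, np.concatenate([gh.ravel(), gJ.ravel()])

    return objective, L * q + n_pairs * q * q


def fit_potts(
    msa: Msa,
    weights: SequenceWeights,
    reg_strength: float = 0.2,
    reg_field: float = 0.01,
    max_iter: int = 150,
    grad_tol: float = 1e-3,
    initial: PottsModel | None = None,
) -> PottsModel:
    """Fit a 21-state Potts model by weighted pseudo-likelihood maximisation.

    Minimises the weighted negative pseudo-log-likelihood plus
    ``reg_field * ||h||^2 + reg_strength * (n_cols - 1) * ||e||^2`` (each
    coupling block counted once), starting from zero parameters (or from
    ``initial`` as a warm start), with L-BFGS to a gradient infinity-norm
    tolerance of ``grad_tol`` or at most ``max_iter`` iterations.
    Non-convergence is recorded in the metadata, not raised.  A
    single-record alignment yields the degenerate, regularizer-dominated
    fit (all couplings near zero).
    """
    X = _encode_potts(msa)
    n, L = X.shape
    if L < 2:
        raise DataError("need at least 2 scored columns to fit couplings")
    q = N_STATES
    tri_i, tri_j = np.triu_indices(L, k=1)
    n_pairs = len(tri_i)

    # most iterations run in float32 (the two big GEMMs dominate the cost),
    # with a float64 polish phase to reach the gradient tolerance (the
    # float32 objective noise floor stalls L-BFGS around max|grad| ~ 5e-3)
    def make_objective(dtype):
        obj, _ = pseudolikelihood_objective(
            msa, weights, reg_strength, reg_field, dtype=dtype
        )
        return obj

    if initial is not None:
        x0 = np.concatenate([initial.fields.ravel(), initial.couplings.ravel()])
    else:
        x0 = np.zeros(L * q + n_pairs * q * q)
    res = minimize(
        make_objective(np.float32),
        x0,
        jac=True,
        method="L-BFGS-B",
        options=dict(maxiter=max_iter, gtol=grad_tol, ftol=1e-12, maxcor=5),
    )
    n_iter = int(res.nit)
    grad_norm = float(np.abs(res.jac).max())
    if grad_norm > grad_tol and n_iter < max_iter:
        res = minimize(
            make_objective(np.float64),
            res.x,
            jac=True,
            method="L-BFGS-B",
            options=dict(
                maxiter=max_iter - n_iter, gtol=grad_tol, ftol=1e-15, maxcor=5
            ),
        )
        n_iter += int(res.nit)
        grad_norm = float(np.abs(res.jac).max())
    converged = grad_norm <= grad_tol
    if not converged:
        logger.warning(
            "Potts fit stopped after %d iterations with max|grad| = %.2e "
            "(tolerance %.1e); returning the partial model",
            n_iter, grad_norm, grad_tol,
        )
    meta = {
        "reg_strength": float(reg_strength),
        "reg_field": float(reg_field),
        "reweight_threshold": weights.threshold,
        "meff": weights.meff,
        "n_iter": n_iter,
        "grad_norm": grad_norm,
        "converged": bool(converged),
        "source": "internal",
    }
    h = res.x[: L * q].reshape(L, q)
    Jp = res.x[L * q :].reshape(n_pairs, q, q)
    return PottsModel(n_cols=L, fields=h, couplings=Jp, metadata=meta)


# ---------------------------------------------------------------------------
# DC scores


def zero_sum_gauge(block: np.ndarray) -> np.ndarray:
    """Zero-sum (Ising) gauge of one coupling block over the 20 aa states."""
    b = block[:N_AA, :N_AA]
    return b - b.mean(axis=0, keepdims=True) - b.mean(axis=1, keepdims=True) + b.mean()


def apc(fro: np.ndarray) -> np.ndarray:
    """Average product correction of a symmetric norm matrix.

    ``APC(i, j) = F(i, j) - mean_i(F) * mean_j(F) / mean(F)`` with all means
    taken over off-diagonal entries.  The diagonal of the result is zero.
    """
    L = fro.shape[0]
    off = ~np.eye(L, dtype=bool)
    row_mean = (fro * off).sum(axis=1) / (L - 1)
    total_mean = (fro * off).sum() / (L * (L - 1))
    corrected = fro - np.outer(row_mean, row_mean) / total_mean
    corrected[~off] = 0.0
    return corrected


def frobenius_apc(model: PottsModel) -> CouplingScores:
    """APC-corrected Frobenius norms of the gauge-fixed coupling blocks.

    Norms run over the 20 amino-acid states only (the gap/other state is
    excluded), after zero-sum gauge transformation of each block.
    """
    L = model.n_cols
    tri_i, tri_j = np.triu_indices(L, k=1)
    blocks = model.couplings[:, :N_AA, :N_AA]
    blocks = (
        blocks
        - blocks.mean(axis=1, keepdims=True)
        - blocks.mean(axis=2, keepdims=True)
        + blocks.mean(axis=(1, 2), keepdims=True)
    )
    norms = np.sqrt((blocks**2).sum(axis=(1, 2)))
    fro = np.zeros((L, L))
    fro[tri_i, tri_j] = norms
    fro += fro.T
    meta = dict(model.metadata)
    return CouplingScores(scores=apc(fro), metadata=meta)


# ---------------------------------------------------------------------------
# interoperability


def import_scores(path, n_cols: int, asym_tol: float = 1e-6) -> CouplingScores:
    """Load a flat L x L numeric score matrix (standard DCA tool output).

    Asymmetries up to ``asym_tol`` are silently symmetrised by averaging;
    anything larger, or a dimension mismatch with the alignment's scored
    column count, is an error.
    """
    try:
        mat = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise DataError(f"cannot parse score matrix {path}: {exc}") from exc
    if mat.shape != (n_cols, n_cols):
        raise DataError(
            f"score matrix {path} has shape {mat.shape}, expected "
            f"({n_cols}, {n_cols}) from the alignment's scored columns"
        )
    asym = float(np.abs(mat - mat.T).max())
    if asym > asym_tol:
        raise DataError(f"score matrix {path} is asymmetric (max |A - A.T| = {asym:g})")
    sym = (mat + mat.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    return CouplingScores(scores=sym, metadata={"source": "imported", "path": str(path)})


def write_scores(scores: CouplingScores, path) -> None:
    """Write the score matrix as flat whitespace-separated numeric text."""
    np.savetxt(path, scores.scores, fmt="%.8g")


def save_model(model: PottsModel, path) -> None:
    """Dump a fitted model (fields, couplings, metadata) as an npz archive."""
    import json

    np.savez_compressed(
        path,
        n_cols=model.n_cols,
        fields=model.fields,
        couplings=model.couplings,
        metadata=json.dumps(model.metadata),
    )


def load_model(path) -> PottsModel:
    """Load a model written by :func:`save_model`."""
    import json

    with np.load(path, allow_pickle=False) as data:
        return PottsModel(
            n_cols=int(data["n_cols"]),
            fields=data["fields"],
            couplings=data["couplings"],
            metadata=json.loads(str(data["metadata"])),
        )


def scores_for_msa(
    msa: Msa,
    reweight_threshold: float = 0.8,
    reg_strength: float = 0.2,
    **fit_kwargs,
) -> CouplingScores:
    """Convenience: reweight, fit, and score one alignment."""
    weights = compute_weights(msa, reweight_threshold)
    model = fit_potts(msa, weights, reg_strength=reg_strength, **fit_kwargs)
    return frobenius_apc(model)
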