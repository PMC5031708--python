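"""Pairwise Granger causality on preprocessed [oxy-Hb] series.

For an ordered channel pair (A, B), channel B "Granger-causes" A when B's
past improves the least-squares prediction of A beyond A's own past.  The
magnitude used throughout the package is Geweke's log variance ratio

    G(B -> A) = ln( sigma^2_reduced(A) / sigma^2_full(A | lags of B) )

with maximum-likelihood (1/T_eff) residual variances, which makes every
defined weight non-negative: at a common order the reduced model is nested
in the full one, so its residual variance cannot be smaller.  (The opposite
ratio, sometimes printed in applied papers, would be non-positive under the
same nesting; magnitudes/"intensities" require this orientation.)

One autoregressive order per pair is selected by minimizing the bivariate
VAR BIC over 1..p_max and shared between both directions and both nested
models, and one :class:`CausalMap` is produced per participant per condition
from the full preprocessed session series.  Causality is strictly bivariate:
no conditioning on the remaining channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, PreconditionError
from .recording import Recording

__all__ = [
    "ARModelFit",
    "CausalMap",
    "fit_ar",
    "select_order_bic",
    "granger_pair",
    "causal_map",
]

DEFAULT_P_MAX = 10  # 1 s of history at 10 Hz


@dataclass(frozen=True)
class ARModelFit:
    """A fitted (possibly augmented) autoregressive model.

    ``resid_var`` is the maximum-likelihood (1/T_eff) mean squared residual;
    ``bic = T_eff*ln(resid_var) + k*ln(T_eff)`` with k the number of
    estimated coefficients (intercept + own lags + optional cross lags).
    """

    order: int
    intercept: float
    own_coefs: np.ndarray
    cross_coefs: np.ndarray | None
    resid_var: float
    n_obs: int
    bic: float
    resid: np.ndarray = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        k = 1 + len(self.own_coefs)
        if self.cross_coefs is not None:
            k += len(self.cross_coefs)
        return k


def _lagmat(x: np.ndarray, p: int) -> np.ndarray:
    """Columns x[t-1], ..., x[t-p] for t = p..T-1 (shape (T-p, p))."""
    T = len(x)
    return np.column_stack([x[p - l:T - l] for l in range(1, p + 1)])


def fit_ar(y: np.ndarray, p: int, x: np.ndarray | None = None) -> ARModelFit:
    """Least-squares AR(p) fit of ``y``, optionally augmented with ``x`` lags.

    The design holds an intercept, p own lags and (if ``x`` is given) p lags
    of the conditioning series; rows run over t = p..T-1.
    """
    y = np.asarray(y, dtype=float)
    if p < 1:
        raise PreconditionError("order p must be >= 1")
    T = len(y)
    if T <= 3 * p + 3:
        raise PreconditionError(f"series of length {T} too short for order {p}")
    if np.ptp(y) == 0:
        raise DegenerateInputError("constant series: singular AR design")
    cols = [np.ones(T - p), _lagmat(y, p)]
    if x is not None:
        x = np.asarray(x, dtype=float)
        if len(x) != T:
            raise PreconditionError("conditioning series must match y in length")
        cols.append(_lagmat(x, p))
    design = np.column_stack(cols)
    target = y[p:]
    beta, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < design.shape[1]:
        raise DegenerateInputError("singular AR design (collinear lagged predictors)")
    resid = target - design @ beta
    t_eff = len(target)
    resid_var = float(resid @ resid) / t_eff
    k = design.shape[1]
    bic = t_eff * np.log(resid_var) + k * np.log(t_eff) if resid_var > 0 else -np.inf
    return ARModelFit(
        order=p,
        intercept=float(beta[0]),
        own_coefs=beta[1:1 + p].copy(),
        cross_coefs=beta[1 + p:].copy() if x is not None else None,
        resid_var=resid_var,
        n_obs=t_eff,
        bic=float(bic),
        resid=resid,
    )


def _var_bic_scan(data: np.ndarray, pairs: np.ndarray, p_max: int) -> np.ndarray:
    """Bivariate-VAR BIC order selection for many pairs at once.

    ``data`` is (T, C); ``pairs`` is (n_pairs, 2) of zero-based channel
    indices.  All candidate orders are scored on the common sample
    t = p_max..T-1 (the standard convention for order selection, so every
    candidate sees identical data), and ties go to the smaller order.
    Returns the selected order per pair.
    """
    T, C = data.shape
    if T <= 3 * p_max + 3:
        raise PreconditionError("series too short for requested p_max")
    rows = T - p_max
    # Z columns: [1, ch0 lags 1..p_max, ch1 lags 1..p_max, ...]
    blocks = [np.ones((rows, 1))]
    for c in range(C):
        blocks.append(np.column_stack(
            [data[p_max - l:T - l, c] for l in range(1, p_max + 1)]
        ))
    Z = np.concatenate(blocks, axis=1)
    Y = data[p_max:]
    G = Z.T @ Z
    ZY = Z.T @ Y
    YY = Y.T @ Y

    n_pairs = len(pairs)
    bics = np.empty((p_max, n_pairs))
    tgt = pairs  # (n_pairs, 2) target channel indices
    syy = YY[tgt[:, :, None], tgt[:, None, :]]  # (n_pairs, 2, 2)
    log_rows = np.log(rows)
    for p in range(1, p_max + 1):
        lag_cols = np.arange(p)  # offsets within a channel block
        cols = np.concatenate(
            [
                np.zeros((n_pairs, 1), dtype=int),
                1 + tgt[:, [0]] * p_max + lag_cols[None, :],
                1 + tgt[:, [1]] * p_max + lag_cols[None, :],
            ],
            axis=1,
        )  # (n_pairs, 2p+1)
        S = G[cols[:, :, None], cols[:, None, :]]
        Sy = ZY[cols][np.arange(n_pairs)[:, None, None],
                      np.arange(cols.shape[1])[None, :, None],
                      tgt[:, None, :]]  # (n_pairs, 2p+1, 2)
        try:
            beta = np.linalg.solve(S, Sy)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(
                S.reshape(-1, S.shape[-1]), Sy.reshape(-1, 2), rcond=None
            )[0]
        sigma = (syy - np.swapaxes(Sy, 1, 2) @ beta) / rows
        sign, logdet = np.linalg.slogdet(sigma)
        logdet = np.where(sign > 0, logdet, np.inf)
        k = 2 * (2 * p + 1)
        bics[p - 1] = rows * logdet + k * log_rows
    return np.argmin(bics, axis=0) + 1  # first minimum -> smaller order on ties


def select_order_bic(a: np.ndarray, b: np.ndarray, p_max: int = DEFAULT_P_MAX) -> int:
    """BIC-minimizing bivariate VAR order for the pair (a, b), over 1..p_max."""
    if p_max < 1:
        raise PreconditionError("p_max must be >= 1")
    if p_max == 1:
        return 1
    data = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    if np.ptp(data[:, 0]) == 0 or np.ptp(data[:, 1]) == 0:
        raise DegenerateInputError("constant series in order selection")
    return int(_var_bic_scan(data, np.array([[0, 1]]), p_max)[0])


def granger_pair(a: np.ndarray, b: np.ndarray, p: int) -> tuple[float, float]:
    """Granger magnitudes ``(G(a->b), G(b->a))`` at a common order ``p``.

    Each magnitude is ``ln(resid_var_reduced / resid_var_full)`` from the
    nested least-squares fits; both are >= 0 up to floating-point round-off
    (clamped at zero), and both are invariant to separate rescaling of the
    two series.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise PreconditionError("series must have equal length")
    red_b = fit_ar(b, p)
    full_b = fit_ar(b, p, x=a)
    red_a = fit_ar(a, p)
    full_a = fit_ar(a, p, x=b)
    if full_a.resid_var <= 0 or full_b.resid_var <= 0:
        raise DegenerateInputError("zero full-model residual variance")
    g_ab = max(0.0, float(np.log(red_b.resid_var / full_b.resid_var)))
    g_ba = max(0.0, float(np.log(red_a.resid_var / full_a.resid_var)))
    return g_ab, g_ba


@dataclass
class CausalMap:
    """Directed Granger weights for one participant under one condition.

    ``weights[i, j]`` is G(channel i+1 -> channel j+1); the diagonal is NaN
    (undefined).  ``orders`` carries the BIC-selected order per pair.
    """

    participant_id: str
    condition: str
    weights: np.ndarray
    orders: np.ndarray
    age: float = np.nan

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    def to_edge_frame(self) -> pd.DataFrame:
        n = self.n_channels
        rows = []
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                rows.append(
                    (self.participant_id, self.condition, i + 1, j + 1,
                     self.weights[i, j], int(self.orders[i, j]))
                )
        return pd.DataFrame(
            rows, columns=["participant", "condition", "from", "to", "weight", "order"]
        )

    def save(self, directory: str | Path) -> Path:
        """Persist as an edge table TSV plus a square-matrix text file."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = f"{self.participant_id}_{self.condition}"
        self.to_edge_frame().to_csv(directory / f"{stem}_edges.tsv", sep="\t",
                                    index=False, float_format="%.12g")
        np.savetxt(directory / f"{stem}_matrix.txt", self.weights, fmt="%.12g",
                   header=f"participant={self.participant_id} condition={self.condition} "
                          f"age={self.age:g}")
        return directory / f"{stem}_edges.tsv"

    @classmethod
    def load(cls, edge_tsv: str | Path, age: float = np.nan) -> "CausalMap":
        df = pd.read_csv(edge_tsv, sep="\t")
        n = int(max(df["from"].max(), df["to"].max()))
        weights = np.full((n, n), np.nan)
        orders = np.zeros((n, n), dtype=int)
        weights[df["from"] - 1, df["to"] - 1] = df["weight"]
        orders[df["from"] - 1, df["to"] - 1] = df["order"]
        return cls(
            participant_id=str(df["participant"].iloc[0]),
            condition=str(df["condition"].iloc[0]),
            weights=weights,
            orders=orders,
            age=age,
        )


def causal_map(rec: Recording, p_max: int = DEFAULT_P_MAX) -> CausalMap:
    """Granger causal map over all ordered channel pairs of a recording.

    For each pair the shared order is selected with the bivariate BIC scan,
    then the two magnitudes come from :func:`granger_pair` at that order.
    A degenerate (constant) channel does not abort the map: its incident
    edges are stored as NaN and a warning is emitted.
    """
    if not rec.preprocessed:
        warnings.warn("computing a causal map on a non-preprocessed recording",
                      stacklevel=2)
    data = rec.data
    n = rec.n_channels
    degenerate = [c for c in range(n) if np.ptp(data[:, c]) == 0
                  or not np.all(np.isfinite(data[:, c]))]
    if degenerate:
        warnings.warn(
            f"degenerate channels {[c + 1 for c in degenerate]}: incident edges "
            "marked missing", stacklevel=2,
        )
    good = [c for c in range(n) if c not in degenerate]
    pairs = np.array(
        [(i, j) for k, i in enumerate(good) for j in good[k + 1:]], dtype=int
    )
    weights = np.full((n, n), np.nan)
    orders = np.zeros((n, n), dtype=int)
    if len(pairs):
        sel = _var_bic_scan(data[:, good], _reindex_pairs(pairs, good), p_max) \
            if len(good) < n else _var_bic_scan(data, pairs, p_max)
        for (i, j), p in zip(pairs, sel):
            g_ij, g_ji = granger_pair(data[:, i], data[:, j], int(p))
            weights[i, j] = g_ij
            weights[j, i] = g_ji
            orders[i, j] = orders[j, i] = int(p)
    return CausalMap(
        participant_id=rec.participant_id,
        condition=rec.condition,
        weights=weights,
        orders=orders,
        age=rec.age,
    )


def _reindex_pairs(pairs: np.ndarray, good: Sequence[int]) -> np.ndarray:
    remap = {c: k for k, c in enumerate(good)}
    return np.array([[remap[i], remap[j]] for i, j in pairs], dtype=int)
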