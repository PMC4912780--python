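"""Per-event linear models for differential splicing.

The measurement model: the (log) signal of a probe is the log of its
(unknown, multiplicative) affinity plus the log of the summed concentration
of the isoforms it interrogates, plus Gaussian noise.  Probe signals are
summarized per event path with Tukey's median polish, giving three values
per sample: y_R (reference), y_1 (path 1), y_2 (path 2).

The user's design matrix D (n samples x k coefficients) is extended with
the fixed lower-triangular ones matrix Q so that the stacked per-path
observations (y_R, y_1, y_2 per sample, in that order) follow a linear
model whose coefficient blocks separate probeset affinities (no interest)
from isoform fold changes.  For a two-condition design the interesting
combinations are b3+b4 = log FC of isoform 1 and b3+b4+b5 = log FC of
isoform 2; each user contrast row is therefore split into the two extended
contrast rows C (x) [1 1 0] and C (x) [1 1 1].

A differential event must move its two isoforms in *opposite* directions:
the two one-tailed p-values (upper tail for isoform 1 up, lower tail for
isoform 2 down) are summed; under the null the sum is triangular on [0, 2]
with mode 1, and the combined two-sided p-value is s^2 for s <= 1 and
(2-s)^2 otherwise.  Variances are moderated across events with the
standard empirical-Bayes squeeze (scaled-F moment matching).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: fixed auxiliary matrix mapping (reference, path1, path2) observations to
#: (affinity/overall, isoform-1, isoform-2) coefficient blocks
Q = np.array([[1, 0, 0],
              [1, 1, 0],
              [1, 1, 1]], dtype=float)

PATH_ORDER = ("Ref", "P1", "P2")

#: contrast modes: which coefficient combination is tested per user contrast
MODES = ("opposite", "b4", "b5", "b4b5")


# ---------------------------------------------------------------------------
# summarization

def median_polish(
    block: np.ndarray, max_iter: int = 100, tol: float = 1e-12
) -> np.ndarray:
    """Summarize a probes x samples block to one value per sample.

    Tukey's median polish: alternately sweep out row (probe) and column
    (sample) medians until the residuals stop changing.  The returned
    per-sample value is overall + column effect; probe (affinity) effects
    are absorbed by the row terms and discarded.
    """
    z = np.asarray(block, dtype=float)
    if z.ndim == 1:
        z = z[None, :]
    if z.size == 0 or not np.all(np.isfinite(z)):
        raise ValueError("median polish needs a finite, non-empty block")
    z = z.copy()
    nr, nc = z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    last = np.abs(z).sum()
    for _ in range(max_iter):
        rmed = np.median(z, axis=1)
        z -= rmed[:, None]
        row += rmed
        delta = np.median(col)
        col -= delta
        overall += delta
        cmed = np.median(z, axis=0)
        z -= cmed[None, :]
        col += cmed
        delta = np.median(row)
        row -= delta
        overall += delta
        total = np.abs(z).sum()
        if abs(last - total) <= tol * max(total, 1.0):
            break
        last = total
    return overall + col


def median_polish_batch(
    blocks: np.ndarray, max_iter: int = 100, tol: float = 1e-12
) -> np.ndarray:
    """Median-polish many equally shaped blocks at once.

    Same sweep schedule as :func:`median_polish`, vectorized over the
    leading axis; each block is frozen as soon as its own residuals stop
    changing, so results are identical to polishing one block at a time.
    Returns an (n_blocks, n_samples) array of overall + column effects.
    """
    z = np.asarray(blocks, dtype=float).copy()
    if z.ndim != 3 or z.size == 0 or not np.all(np.isfinite(z)):
        raise ValueError("batch median polish needs finite (B, r, c) blocks")
    nb, nr, nc = z.shape
    overall = np.zeros(nb)
    row = np.zeros((nb, nr))
    col = np.zeros((nb, nc))
    last = np.abs(z).sum(axis=(1, 2))
    active = np.ones(nb, dtype=bool)
    for _ in range(max_iter):
        a = active
        rmed = np.median(z[a], axis=2)
        z[a] -= rmed[:, :, None]
        row[a] += rmed
        delta = np.median(col[a], axis=1)
        col[a] -= delta[:, None]
        overall[a] += delta
        cmed = np.median(z[a], axis=1)
        z[a] -= cmed[:, None, :]
        col[a] += cmed
        delta = np.median(row[a], axis=1)
        row[a] -= delta[:, None]
        overall[a] += delta
        total = np.abs(z[a]).sum(axis=(1, 2))
        done = np.abs(last[a] - total) <= tol * np.maximum(total, 1.0)
        last[a] = total
        idx = np.flatnonzero(a)
        active[idx[done]] = False
        if not active.any():
            break
    return overall[:, None] + col


def quantile_normalize(signals: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) to share the mean sorted profile."""
    ranks = signals.rank(method="first").to_numpy().astype(int) - 1
    mean_profile = np.sort(signals.to_numpy(), axis=0).mean(axis=1)
    return pd.DataFrame(
        mean_profile[ranks], index=signals.index, columns=signals.columns
    )


@dataclass
class PathSignals:
    """Summarized per-event path signals.

    ``values`` has shape (n_events, n_samples, 3), path order (Ref, P1, P2)
    per sample; flattening sample-major reproduces the stacked observation
    vector of the extended linear model.
    """

    event_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    @property
    def stacked(self) -> np.ndarray:
        """(n_events, 3 * n_samples) in (y_R, y_1, y_2)-per-sample order."""
        return self.values.reshape(len(self.event_ids), -1)

    def path_max(self, path: str) -> np.ndarray:
        """Per-event max over samples for one path."""
        return self.values[:, :, PATH_ORDER.index(path)].max(axis=1)


def summarize_events(
    signals: pd.DataFrame, probeset_map, sample_ids: list[str] | None = None
) -> PathSignals:
    """Median-polish every event-path probeset into per-sample values."""
    if sample_ids is None:
        sample_ids = list(signals.columns)
    mat = signals[sample_ids]
    probe_rows = {p: i for i, p in enumerate(mat.index)}
    arr = mat.to_numpy(dtype=float)

    table = probeset_map.table
    grouped: dict[str, dict[str, list[int]]] = {}
    for event_id, path, probe_id in table.itertuples(index=False):
        if probe_id in probe_rows:
            grouped.setdefault(event_id, {}).setdefault(path, []).append(
                probe_rows[probe_id]
            )
    event_ids = [
        ev for ev in grouped
        if all(grouped[ev].get(p) for p in PATH_ORDER)
    ]
    dropped = set(grouped) - set(event_ids)
    if dropped:
        logger.warning("%d events dropped: probes missing from the signal "
                       "matrix", len(dropped))
    values = np.empty((len(event_ids), len(sample_ids), 3))
    for j, path in enumerate(PATH_ORDER):
        by_size: dict[int, list[int]] = {}
        for i, ev in enumerate(event_ids):
            by_size.setdefault(len(grouped[ev][path]), []).append(i)
        for size, idx in by_size.items():
            rows = np.array([grouped[event_ids[i]][path] for i in idx])
            values[idx, :, j] = median_polish_batch(arr[rows])
    return PathSignals(event_ids=event_ids, sample_ids=list(sample_ids),
                       values=values)


# ---------------------------------------------------------------------------
# design and contrast extension

def extend_design(D: np.ndarray) -> np.ndarray:
    """Kronecker-extend a design matrix: D_DRS = D (x) Q (3n x 3k)."""
    D = np.atleast_2d(np.asarray(D, dtype=float))
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return np.kron(D, Q)


def extend_contrast(C: np.ndarray, mode: str = "opposite") -> np.ndarray:
    """Extended contrast rows testing per-isoform usage.

    In the default (opposite-direction) mode each user contrast row c
    becomes the pair c (x) [1 1 0] (isoform 1 log FC, i.e. b3+b4 per
    condition block) followed by c (x) [1 1 1] (isoform 2 log FC,
    b3+b4+b5); all first-member rows come first, then all second-member
    rows.  The single-contrast modes test b4, b5 or b4+b5 directly and are
    intended for pre-filtered signals.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if mode == "opposite":
        return np.vstack([np.kron(C, np.array([[1.0, 1.0, 0.0]])),
                          np.kron(C, np.array([[1.0, 1.0, 1.0]]))])
    if mode == "b4":
        return np.kron(C, np.array([[0.0, 1.0, 0.0]]))
    if mode == "b5":
        return np.kron(C, np.array([[0.0, 0.0, 1.0]]))
    if mode == "b4b5":
        return np.kron(C, np.array([[0.0, 1.0, 1.0]]))
    raise ValueError(f"unknown contrast mode {mode!r}")


@dataclass
class DesignSpec:
    """User design/contrast matrices plus their Kronecker extensions."""

    D: np.ndarray
    C: np.ndarray
    mode: str = "opposite"
    D_DRS: np.ndarray = field(init=False)
    C_DRS: np.ndarray = field(init=False)

    def __post_init__(self):
        self.D = np.atleast_2d(np.asarray(self.D, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        if self.C.shape[1] != self.D.shape[1]:
            raise ValueError(
                f"contrast has {self.C.shape[1]} columns but design has "
                f"{self.D.shape[1]} coefficients"
            )
        if not np.any(self.C):
            raise ValueError("contrast matrix is all zeros")
        if self.mode not in MODES:
            raise ValueError(f"unknown contrast mode {self.mode!r}")
        self.D_DRS = extend_design(self.D)
        self.C_DRS = extend_contrast(self.C, mode=self.mode)

    @property
    def n_samples(self) -> int:
        return self.D.shape[0]

    @property
    def n_user_contrasts(self) -> int:
        return self.C.shape[0]


# ---------------------------------------------------------------------------
# fitting

@dataclass
class EventFits:
    """Least-squares fits of the extended model for a batch of events."""

    event_ids: list[str]
    coef: np.ndarray            # (n_events, 3k)
    contrast_est: np.ndarray    # (n_events, n_extended_contrasts)
    contrast_var_factor: np.ndarray  # (n_extended_contrasts,) c'(X'X)^-1 c
    s2: np.ndarray              # residual variances
    df_residual: float


def fit_events(path_signals: PathSignals, design: DesignSpec) -> EventFits:
    """Solve the stacked per-event linear system by least squares.

    All events share the design, so one pseudo-inverse serves the batch.
    Residual df is 3n - 3k; events need more observations than
    coefficients (3n > 3k) or fitting refuses.
    """
    X = design.D_DRS
    Y = path_signals.stacked
    if Y.shape[1] != X.shape[0]:
        raise ValueError(
            f"path signals have {Y.shape[1]} observations per event but the "
            f"extended design has {X.shape[0]} rows"
        )
    n_obs, n_coef = X.shape
    df = n_obs - n_coef
    if df <= 0:
        raise ValueError("not enough samples: 3n must exceed 3k")
    pinv = np.linalg.pinv(X)
    coef = Y @ pinv.T
    resid = Y - coef @ X.T
    s2 = (resid ** 2).sum(axis=1) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    Cx = design.C_DRS
    contrast_est = coef @ Cx.T
    var_factor = np.einsum("ij,jk,ik->i", Cx, xtx_inv, Cx)
    return EventFits(
        event_ids=list(path_signals.event_ids),
        coef=coef,
        contrast_est=contrast_est,
        contrast_var_factor=var_factor,
        s2=s2,
        df_residual=float(df),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderate_variances(
    s2: np.ndarray, df: float
) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes squeeze of per-event residual variances.

    Assumes a scaled inverse-chi-square prior; the prior df d0 and prior
    variance s0^2 are moment-matched on log s^2 against the scaled-F
    marginal.  Returns (posterior variances, d0, s0^2); the moderated t
    statistics then use d0 + df degrees of freedom.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if positive.sum() < 2:
        warnings.warn("fewer than 2 events with positive residual variance; "
                      "variances left unmoderated")
        return s2.copy(), 0.0, float(np.median(s2))
    z = np.log(s2[positive])
    evar = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 1e-12:
        # no excess spread beyond chi-square sampling noise: infinite prior
        # df, every variance shrunk fully onto the common value
        s02 = float(np.exp(z.mean()))
        return np.full_like(s2, s02), np.inf, s02
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = float(np.exp(
        z.mean()
        - special.digamma(df / 2.0) + np.log(df / 2.0)
        + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    ))
    post = (d0 * s02 + df * s2) / (d0 + df)
    return post, float(d0), s02


# ---------------------------------------------------------------------------
# p-value combination and filtering

def combine_pvalues(p_a, p_b):
    """Combine two one-tailed p-values through their triangular null sum.

    Under the null s = p_a + p_b is triangular on [0, 2] with mode 1; the
    combined two-sided p-value is the probability of a sum at least as far
    from 1: s^2 for s <= 1 and (2 - s)^2 for s > 1.  Orientation makes
    s -> 0 mean "isoform 1 up and isoform 2 down" and s -> 2 the reverse,
    so only opposite-direction changes become significant.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if np.any((p_a < 0) | (p_a > 1)) or np.any((p_b < 0) | (p_b > 1)):
        raise ValueError("one-tailed p-values must lie in [0, 1]")
    s = p_a + p_b
    return np.where(s <= 1.0, s ** 2, (2.0 - s) ** 2)


def expression_filter(
    path_signals: PathSignals, quantile: float
) -> tuple[np.ndarray, float]:
    """Flag events whose three paths are all expressed above threshold.

    The threshold is the requested quantile (type-7, linear interpolation)
    of the per-event maxima of the *reference* path across samples; an
    event passes when each of its three paths has max-over-samples signal
    above the threshold.
    """
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must lie in [0, 1]")
    ref_max = path_signals.path_max("Ref")
    threshold = float(np.quantile(ref_max, quantile, method="linear"))
    maxima = path_signals.values.max(axis=1)  # (n_events, 3)
    expressed = np.all(maxima > threshold, axis=1)
    return expressed, threshold


def splicing_index(
    probeset_signal: np.ndarray,
    gene_signal: np.ndarray,
    cond1: np.ndarray,
    cond2: np.ndarray,
    log2_input: bool = True,
) -> tuple[float, float]:
    """Ratio-of-ratios splicing index (comparison baseline).

    SI = (probeset/gene signal ratio in condition 1) divided by the same
    ratio in condition 2, on the linear scale.  SI near 1 means the
    probeset tracks the gene; returns (SI, log2 SI).  A zero gene signal
    makes the index undefined (NaN).
    """
    ps = np.asarray(probeset_signal, dtype=float)
    gs = np.asarray(gene_signal, dtype=float)
    if log2_input:
        ps, gs = 2.0 ** ps, 2.0 ** gs
    g1, g2 = gs[cond1].mean(), gs[cond2].mean()
    if g1 == 0 or g2 == 0:
        logger.warning("splicing index undefined: zero gene signal")
        return float("nan"), float("nan")
    si = (ps[cond1].mean() / g1) / (ps[cond2].mean() / g2)
    return float(si), float(np.log2(si)) if si > 0 else float("nan")


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# full statistics stage

def test_events(
    path_signals: PathSignals,
    design: DesignSpec,
    quantile: float = 0.25,
    moderated_df: bool = True,
) -> pd.DataFrame:
    """Fit, moderate, combine and filter: one row per event per contrast.

    Returns a table sorted by combined p-value (ties broken by the
    magnitude of the isoform log-FC separation) with columns for the two
    per-isoform log fold changes, moderated t statistics, the one-tailed
    p-values and their sum, the combined p, its BH adjustment and the
    expression flag.
    """
    fits = fit_events(path_signals, design)
    s2_post, d0, s02 = moderate_variances(fits.s2, fits.df_residual)
    df_total = fits.df_residual + (d0 if moderated_df else 0.0)
    se = np.sqrt(np.outer(s2_post, fits.contrast_var_factor))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = fits.contrast_est / se
    tdist = stats.norm if np.isinf(df_total) else stats.t(df=df_total)

    expressed, threshold = expression_filter(path_signals, quantile)
    m = design.n_user_contrasts
    frames = []
    for ci in range(m):
        if design.mode == "opposite":
            t_a = tstat[:, ci]
            t_b = tstat[:, m + ci]
            p_a = tdist.sf(t_a)          # isoform 1 up
            p_b = tdist.cdf(t_b)         # isoform 2 down
            s = p_a + p_b
            combined = combine_pvalues(p_a, p_b)
            lfc1 = fits.contrast_est[:, ci]
            lfc2 = fits.contrast_est[:, m + ci]
        else:
            t_a = tstat[:, ci]
            t_b = np.full_like(t_a, np.nan)
            p_a = 2.0 * tdist.sf(np.abs(t_a))
            p_b = np.full_like(t_a, np.nan)
            s = np.full_like(t_a, np.nan)
            combined = p_a
            lfc1 = fits.contrast_est[:, ci]
            lfc2 = np.full_like(t_a, np.nan)
        frames.append(pd.DataFrame({
            "event_id": fits.event_ids,
            "contrast": ci,
            "logFC_path1": lfc1,
            "logFC_path2": lfc2,
            "t_path1": t_a,
            "t_path2": t_b,
            "p_path1": p_a,
            "p_path2": p_b,
            "pvalue_sum": s,
            "pvalue": combined,
            "padj": adjust_fdr(combined),
            "expressed": expressed,
        }))
    out = pd.concat(frames, ignore_index=True)
    out["_sep"] = -np.abs(out.logFC_path1 - out.logFC_path2.fillna(0.0))
    out = (out.sort_values(["pvalue", "_sep", "event_id"])
              .drop(columns="_sep").reset_index(drop=True))
    out.attrs["expression_threshold"] = threshold
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s02
    return out
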