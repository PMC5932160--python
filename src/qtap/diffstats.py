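"""S0-moderated two-group testing with permutation-based FDR.

Per protein the statistic is d* = D / (s + S0), where D is the mock minus
treatment difference of group means (log2 units), s the two-sample standard
error (pooled Student by default, Welch optional) and S0 a small constant
that damps rows whose tiny variance would otherwise make a negligible
difference look significant (SAM-style moderation). The unmoderated t and
its two-sided p-value are kept alongside for the volcano plot.

Significance is decided by a label-permutation null: all distinct
reassignments of samples to the two groups (exhaustive when their number is
small, a 4v4 design has C(8,4)-1 = 69, else a seeded uniform
sample) are used to estimate, at every candidate cutoff c taken from the
observed |d*|, FDR(c) = mean permuted exceedances / observed exceedances.
The curve is capped at 1, made monotone non-increasing in c by a cumulative
minimum (q-value convention), and the smallest c with FDR(c) <= alpha is the
decision threshold. No pi0 factor is applied, which leaves the estimate
conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, PermutationError, StatisticError
from .tables_io import ProteinTable, SampleDesign

#: numerical floor for p-values of zero-variance rows (keeps p in (0, 1])
_P_FLOOR = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class FdrParams:
    s0: float = 0.1
    alpha: float = 0.05
    n_perm: Union[int, str] = 250
    seed: int = 0
    test_variant: Literal["pooled_student", "welch"] = "pooled_student"
    exhaustive_cap: int = 10_000

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ConfigError("s0 must be non-negative")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if isinstance(self.n_perm, str):
            if self.n_perm != "exhaustive":
                raise ConfigError(f"n_perm must be an integer or 'exhaustive'")
        elif self.n_perm < 1:
            raise ConfigError("n_perm must be positive")
        if self.test_variant not in ("pooled_student", "welch"):
            raise ConfigError(f"unknown test variant {self.test_variant!r}")


@dataclass(frozen=True)
class ModeratedT:
    difference: float
    se: float
    d_mod: float
    t: float
    p: float
    df: float


def _group_moments(X: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Row means and unbiased variances over the masked sample columns.

    ``X`` is (rows, samples); ``mask`` is (P, samples) boolean with a fixed
    per-row count n. Returns means (rows, P), variances (rows, P), n.

    Moments are taken per assignment with numpy's own reductions rather than
    one matmul over all assignments: the complete label swap must reproduce
    the observed statistic bit-for-bit (ties at the observed thresholds are
    exact), which shape-dependent BLAS summation does not guarantee.
    """
    n = int(mask[0].sum())
    P = mask.shape[0]
    mean = np.empty((X.shape[0], P))
    var = np.empty_like(mean)
    for k in range(P):
        sub = X[:, mask[k]]
        mean[:, k] = sub.mean(axis=1)
        var[:, k] = sub.var(axis=1, ddof=1)
    return mean, var, n


def _dstar(
    X: np.ndarray,
    masks: np.ndarray,
    s0: float,
    variant: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(D, se, d*, df) for every row under every label assignment."""
    mean1, var1, n1 = _group_moments(X, masks)
    mean2, var2, n2 = _group_moments(X, ~masks)
    D = mean1 - mean2
    if variant == "pooled_student":
        df_val = n1 + n2 - 2
        sp2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / df_val
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = np.full_like(D, float(df_val))
    else:
        a, b = var1 / n1, var2 / n2
        se = np.sqrt(a + b)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (a + b) ** 2 / (a * a / (n1 - 1) + b * b / (n2 - 1))
        df = np.where(np.isfinite(df), df, float(n1 + n2 - 2))
    dstar = np.divide(
        D, se + s0, out=np.zeros_like(D), where=(se + s0) > 0
    )
    return D, se, dstar, df


def _t_and_p(D: np.ndarray, se: np.ndarray, df: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, D / np.where(se > 0, se, 1.0), np.where(D == 0, 0.0, np.inf * np.sign(D)))
    p = np.empty_like(t, dtype=float)
    finite = np.isfinite(t)
    p[finite] = 2.0 * sps.t.sf(np.abs(t[finite]), df[finite])
    p[~finite] = 0.0
    return t, np.clip(p, _P_FLOOR, 1.0)


def moderated_t(
    values_mock: np.ndarray,
    values_treatment: np.ndarray,
    s0: float = 0.1,
    variant: Literal["pooled_student", "welch"] = "pooled_student",
) -> ModeratedT:
    """Two-group S0-moderated statistic for a single protein.

    D = mean(mock) - mean(treatment); d* = D / (s + S0); t = D / s with the
    two-sided p from the t distribution. Both groups need >= 2 finite values
    (the matrix is complete after imputation). A zero-variance row with a
    non-zero difference is undefined at S0 = 0 and raises; S0 > 0
    regularizes it (t remains infinite, p is floored at the smallest
    positive float).
    """
    x = np.asarray(values_mock, dtype=float)
    y = np.asarray(values_treatment, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatisticError("each group needs at least two values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise StatisticError("non-finite values; impute before testing")
    X = np.concatenate([x, y])[None, :]
    mask = np.zeros((1, x.size + y.size), dtype=bool)
    mask[0, : x.size] = True
    D, se, dstar, df = _dstar(X, mask, s0, variant)
    d, s = float(D[0, 0]), float(se[0, 0])
    if s == 0 and d != 0 and s0 == 0:
        raise StatisticError("zero variance with non-zero difference and s0=0")
    t, p = _t_and_p(D, se, df)
    return ModeratedT(
        difference=d,
        se=s,
        d_mod=float(dstar[0, 0]),
        t=float(t[0, 0]),
        p=float(p[0, 0]),
        df=float(df[0, 0]),
    )


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


@dataclass
class PermutationNull:
    """Label assignments used for the null and the derived FDR curve."""

    assignments: np.ndarray      # (P, samples) bool, True = relabeled "mock"
    dstar_perm: np.ndarray       # (rows, P)
    thresholds: np.ndarray       # ascending candidate cutoffs (observed |d*|)
    fdr_raw: np.ndarray          # capped estimate per threshold
    fdr: np.ndarray              # monotone (cumulative-minimum) estimate
    exhaustive: bool


@dataclass
class FdrResult:
    threshold: float             # on |d*|; inf when nothing is callable
    flags: np.ndarray            # per-row significance, aligned with the table
    null: PermutationNull


def _identity_mask(design: SampleDesign, columns: list[str]) -> np.ndarray:
    mock = set(design.mock_samples)
    return np.array([c in mock for c in columns], dtype=bool)


def _all_assignments(n_samples: int, n_mock: int) -> np.ndarray:
    idx = list(combinations(range(n_samples), n_mock))
    masks = np.zeros((len(idx), n_samples), dtype=bool)
    for k, cols in enumerate(idx):
        masks[k, list(cols)] = True
    return masks


def permutation_assignments(
    design: SampleDesign,
    columns: list[str],
    params: FdrParams,
) -> tuple[np.ndarray, bool]:
    """Non-identity label assignments: exhaustive when feasible, else sampled."""
    identity = _identity_mask(design, columns)
    n, n1 = len(columns), int(identity.sum())
    total = math.comb(n, n1)
    if total - 1 < 2:
        raise PermutationError(
            "fewer than 2 distinct non-identity label assignments; add replicates"
        )
    exhaustive_requested = params.n_perm == "exhaustive"
    if exhaustive_requested and total - 1 > params.exhaustive_cap:
        raise PermutationError(
            f"exhaustive enumeration over {total - 1} assignments exceeds the cap "
            f"({params.exhaustive_cap})"
        )
    feasible = total - 1 <= params.exhaustive_cap
    want = None if exhaustive_requested else int(params.n_perm)
    if feasible and (exhaustive_requested or want >= total - 1):
        masks = _all_assignments(n, n1)
        keep = ~(masks == identity).all(axis=1)
        return masks[keep], True
    rng = np.random.default_rng(params.seed)
    if total <= 200_000:
        masks = _all_assignments(n, n1)
        keep = np.nonzero(~(masks == identity).all(axis=1))[0]
        pick = rng.choice(keep, size=want, replace=False)
        return masks[np.sort(pick)], False
    # designs too large to enumerate: rejection-sample distinct assignments
    seen: set[bytes] = {identity.tobytes()}
    out = []
    while len(out) < want:
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n1, replace=False)] = True
        key = mask.tobytes()
        if key not in seen:
            seen.add(key)
            out.append(mask)
    return np.array(out), False


def fdr_curve(
    abs_obs: np.ndarray, abs_perm: np.ndarray, n_perm: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Estimated FDR at every candidate threshold taken from |d*| observed.

    raw FDR(c) = mean permuted exceedances / max(1, observed exceedances),
    capped at 1; the monotone curve is the running minimum over c' <= c,
    which is non-increasing in c.
    """
    thresholds = np.unique(abs_obs)  # ascending
    sorted_obs = np.sort(abs_obs)
    sorted_perm = np.sort(abs_perm.ravel())
    obs_ge = abs_obs.size - np.searchsorted(sorted_obs, thresholds, side="left")
    perm_ge = (sorted_perm.size - np.searchsorted(sorted_perm, thresholds, side="left")) / n_perm
    raw = np.minimum(1.0, perm_ge / np.maximum(1, obs_ge))
    monotone = np.minimum.accumulate(raw)
    return thresholds, raw, monotone


def permutation_fdr(
    table: ProteinTable, design: SampleDesign, params: FdrParams
) -> FdrResult:
    """Permutation-based FDR thresholding of the moderated statistics.

    Requires a complete (post-imputation) matrix. Rows are flagged
    significant when |d*| reaches the smallest candidate threshold whose
    monotone FDR estimate is <= alpha.
    """
    columns = table.sample_columns
    X = table.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ConfigError("matrix contains missing values; impute before testing")
    identity = _identity_mask(design, columns)
    if identity.sum() < 2 or (~identity).sum() < 2:
        raise ConfigError("each group needs at least 2 samples")

    _, _, dstar_obs, _ = _dstar(X, identity[None, :], params.s0, params.test_variant)
    dstar_obs = dstar_obs[:, 0]
    masks, exhaustive = permutation_assignments(design, columns, params)
    _, _, dstar_perm, _ = _dstar(X, masks, params.s0, params.test_variant)

    abs_obs = np.abs(dstar_obs)
    thresholds, raw, monotone = fdr_curve(abs_obs, np.abs(dstar_perm), masks.shape[0])
    callable_idx = np.nonzero(monotone <= params.alpha)[0]
    if callable_idx.size:
        threshold = float(thresholds[callable_idx[0]])
        flags = abs_obs >= threshold
    else:
        threshold = float("inf")
        flags = np.zeros_like(abs_obs, dtype=bool)
    null = PermutationNull(
        assignments=masks,
        dstar_perm=dstar_perm,
        thresholds=thresholds,
        fdr_raw=raw,
        fdr=monotone,
        exhaustive=exhaustive,
    )
    return FdrResult(threshold=threshold, flags=flags, null=null)


# ---------------------------------------------------------------------------
# per-row results and the volcano table
# ---------------------------------------------------------------------------


def differential_analysis(
    table: ProteinTable, design: SampleDesign, params: FdrParams
) -> tuple[pd.DataFrame, FdrResult]:
    """Full per-protein results frame plus the permutation-FDR decision.

    The frame carries, per protein group: group means, difference
    (log2 mock/treatment), standard error, moderated d*, unmoderated t,
    two-sided p, -log10 p and the significance flag.
    """
    columns = table.sample_columns
    X = table.values.to_numpy(dtype=float)
    identity = _identity_mask(design, columns)
    D, se, dstar, df = _dstar(X, identity[None, :], params.s0, params.test_variant)
    t, p = _t_and_p(D, se, df)
    fdr = permutation_fdr(table, design, params)
    frame = pd.DataFrame(
        {
            "group_id": table.records.index.to_numpy(),
            "gene_label": table.records["gene_label"].to_numpy(),
            "mean_mock": X[:, identity].mean(axis=1),
            "mean_treatment": X[:, ~identity].mean(axis=1),
            "difference": D[:, 0],
            "se": se[:, 0],
            "d_mod": dstar[:, 0],
            "t_statistic": t[:, 0],
            "p_value": p[:, 0],
            "neg_log10_p": -np.log10(p[:, 0]),
            "significant": fdr.flags,
        }
    )
    return frame, fdr


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Two-column volcano core (x = log2 mock/treatment, y = -log10 p) + flag."""
    return results[["group_id", "gene_label", "difference", "neg_log10_p", "significant"]].copy()


def volcano_plot(
    results: pd.DataFrame,
    path,
    *,
    title: str | None = None,
    label_significant: bool = True,
) -> None:
    """Render the volcano as PNG/SVG; significant points are labeled."""
    from matplotlib.figure import Figure

    fig = Figure(figsize=(6, 5))
    ax = fig.subplots()
    sig = results["significant"].to_numpy(dtype=bool)
    ax.scatter(
        results.loc[~sig, "difference"],
        results.loc[~sig, "neg_log10_p"],
        s=10,
        c="0.6",
        label="not significant",
    )
    ax.scatter(
        results.loc[sig, "difference"],
        results.loc[sig, "neg_log10_p"],
        s=14,
        c="crimson",
        label="significant",
    )
    if label_significant:
        for _, row in results[sig].iterrows():
            label = row["gene_label"] or row["group_id"]
            ax.annotate(label, (row["difference"], row["neg_log10_p"]), fontsize=6)
    ax.axvline(0.0, lw=0.5, c="0.8")
    ax.set_xlabel("log2(mock/treatment)")
    ax.set_ylabel("−log10 p")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
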