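"""Shared test utilities: table builders and independent oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from qtap.tables_io import MOCK, TREATMENT, ProteinTable, SampleDesign, SampleInfo


def make_design(n_mock: int = 4, n_treat: int = 4, bait_id: str = "SMXL7") -> SampleDesign:
    samples = [SampleInfo(f"mock_r{i+1}", MOCK, i + 1) for i in range(n_mock)] + [
        SampleInfo(f"treat_r{i+1}", TREATMENT, i + 1) for i in range(n_treat)
    ]
    return SampleDesign(samples=tuple(samples), bait_id=bait_id)


def make_table(
    values,
    ids=None,
    samples=None,
    scale="log2",
    bait=None,
    reverse=(),
    contaminant=(),
    site=(),
):
    """Build a ProteinTable from a 2-D array-like (NaN = missing)."""
    arr = np.asarray(values, dtype=float)
    n, m = arr.shape
    if ids is None:
        ids = [f"P{i+1:02d}" for i in range(n)]
    if samples is None:
        half = m // 2
        samples = [f"mock_r{i+1}" for i in range(half)] + [
            f"treat_r{i+1}" for i in range(m - half)
        ]
    records = pd.DataFrame(
        {
            "gene_label": ids,
            "unique_peptides": 2,
            "is_reverse": [i in reverse for i in ids],
            "is_contaminant": [i in contaminant for i in ids],
            "only_by_site": [i in site for i in ids],
            "is_bait": [i == bait for i in ids],
        },
        index=pd.Index(ids, name="group_id"),
    )
    values_df = pd.DataFrame(arr, index=records.index, columns=samples)
    return ProteinTable(records=records, values=values_df, scale=scale)


# ---------------------------------------------------------------------------
# brute-force permutation-FDR oracle (pure python loops, np.mean/np.var only)
# ---------------------------------------------------------------------------


def brute_force_permutation_fdr(X, mock_cols, s0, alpha):
    """Enumerate every label assignment and estimate the FDR curve by loops.

    Returns dict with observed d*, thresholds, raw and monotone FDR
    estimates, the selected threshold and per-row flags.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    n1 = len(mock_cols)
    n2 = n - n1

    def row_dstar(row, cols):
        g1 = np.array([row[j] for j in cols])
        g2 = np.array([row[j] for j in range(n) if j not in cols])
        m1, m2 = np.mean(g1), np.mean(g2)
        v1 = np.var(g1, ddof=1)
        v2 = np.var(g2, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        return (m1 - m2) / (se + s0)

    def all_dstar(cols):
        return np.array([row_dstar(row, cols) for row in X])

    obs = all_dstar(tuple(mock_cols))
    identity = frozenset(mock_cols)
    perm_cols = [
        c for c in itertools.combinations(range(n), n1) if frozenset(c) != identity
    ]
    null = [all_dstar(c) for c in perm_cols]

    thresholds = np.unique(np.abs(obs))
    raw = []
    for c in thresholds:
        num = np.mean([int(np.sum(np.abs(d) >= c)) for d in null])
        den = max(1, int(np.sum(np.abs(obs) >= c)))
        raw.append(min(1.0, num / den))
    raw = np.array(raw)
    monotone = np.minimum.accumulate(raw)
    hit = np.nonzero(monotone <= alpha)[0]
    threshold = float(thresholds[hit[0]]) if hit.size else float("inf")
    flags = np.abs(obs) >= threshold
    return {
        "dstar_obs": obs,
        "n_assignments": len(perm_cols),
        "thresholds": thresholds,
        "fdr_raw": raw,
        "fdr": monotone,
        "threshold": threshold,
        "flags": flags,
    }
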