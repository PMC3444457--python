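"""Category over-representation statistics for GO/KEGG-style gene sets.

For a category with counts (n_f differential genes in the category, n
category genes on the platform, N_f differential genes overall, N platform
genes) the module computes a one-sided Fisher exact p-value, a Pearson
chi-squared p-value on the same 2×2 table (no continuity correction), the
enrichment ratio

    Re = (n_f / n) / (N_f / N),

and two false-discovery summaries: a batch-level FDR derived from the
Fisher-vs-chi-squared comparison (N_k = number of categories whose Fisher
p is below their chi-squared p; fdr = 1 - N_k / T), and standard per-
category Benjamini–Hochberg q-values.  The comparison-based FDR is
reconstructed from a definition that survives only in fragmentary form in
the literature this follows; BH is emitted alongside so users need not rely
on the reconstruction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSetCollection
from .rvm import adjust_fdr_bh


def _validate_counts(n_f: int, n: int, N_f: int, N: int) -> None:
    if min(n_f, n, N_f, N) < 0:
        raise ValueError("counts must be non-negative")
    if n > N or N_f > N:
        raise ValueError("category and differential counts cannot exceed the universe")
    if n_f > min(n, N_f):
        raise ValueError("n_f cannot exceed min(n, N_f)")


def fisher_exact_p(n_f: int, n: int, N_f: int, N: int) -> float:
    """One-sided over-representation p-value: P(X >= n_f) for
    X ~ Hypergeometric(N, N_f, n)."""
    _validate_counts(n_f, n, N_f, N)
    return float(stats.hypergeom.sf(n_f - 1, N, N_f, n))


def chi2_p(n_f: int, n: int, N_f: int, N: int) -> float:
    """Pearson chi-squared p-value on the 2×2 membership × status table.

    One degree of freedom, no continuity correction.  Returns NaN when any
    expected cell count is zero (the statistic is undefined; such records
    are excluded from the Fisher-vs-chi-squared FDR rule).
    """
    _validate_counts(n_f, n, N_f, N)
    obs = np.array(
        [[n_f, n - n_f], [N_f - n_f, N - n - N_f + n_f]], dtype=float
    )
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total == 0:
        return float("nan")
    expected = row @ col / total
    if (expected == 0).any():
        return float("nan")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def enrichment_ratio(n_f: int, n: int, N_f: int, N: int) -> float:
    """Observed over expected representation: Re = (n_f/n) / (N_f/N)."""
    _validate_counts(n_f, n, N_f, N)
    if n == 0:
        raise ValueError("category size n must be positive")
    if N_f == 0:
        raise ValueError("there are no differential genes (N_f = 0)")
    if N == 0:
        raise ValueError("universe size N must be positive")
    return (n_f / n) / (N_f / N)


def fisher_chi2_fdr(p_fisher: np.ndarray, p_chi2: np.ndarray) -> float:
    """Batch FDR from the Fisher-vs-chi-squared comparison.

    N_k is the number of categories whose Fisher p-value is strictly below
    their chi-squared p-value; the FDR for the batch is 1 - N_k / T.
    Records with an undefined chi-squared p (NaN) are excluded from both
    N_k and T.
    """
    pf = np.asarray(p_fisher, dtype=float)
    pc = np.asarray(p_chi2, dtype=float)
    if pf.shape != pc.shape:
        raise ValueError("p-value lists must have the same length")
    if pf.size == 0:
        raise ValueError("need at least one category")
    valid = ~np.isnan(pc) & ~np.isnan(pf)
    T = int(valid.sum())
    if T == 0:
        raise ValueError("no category has a defined chi-squared p-value")
    n_k = int((pf[valid] < pc[valid]).sum())
    return 1.0 - n_k / T


def enrich(
    differential_genes: set[str],
    universe: set[str],
    sets: GeneSetCollection,
    p_threshold: float = 0.05,
    min_category_size: int = 1,
) -> pd.DataFrame:
    """Over-representation scan of every eligible category.

    Category gene lists are intersected with the universe before counting.
    Returns one record per category of intersected size >=
    ``min_category_size``, sorted by Fisher p ascending (ties: descending
    Re, then category id), with the batch fisher/chi2 FDR attached to every
    record and per-category BH q-values alongside.  Categories with Fisher
    p < p_threshold are flagged significant.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    differential = set(differential_genes)
    stray = differential - universe
    if stray:
        raise ValueError(
            f"differential gene {sorted(stray)[0]!r} is not in the universe"
        )
    N = len(universe)
    N_f = len(differential)
    rows = []
    for name in sets:
        members = sets[name] & universe
        n = len(members)
        if n < min_category_size or n == 0:
            continue
        n_f = len(members & differential)
        pf = fisher_exact_p(n_f, n, N_f, N)
        pc = chi2_p(n_f, n, N_f, N)
        re = enrichment_ratio(n_f, n, N_f, N) if N_f > 0 else 0.0
        rows.append((name, sets.description(name), n_f, n, N_f, N, pf, pc, re))
    frame = pd.DataFrame(
        rows,
        columns=[
            "category",
            "description",
            "n_f",
            "n",
            "N_f",
            "N",
            "p_fisher",
            "p_chi2",
            "re",
        ],
    )
    if frame.empty:
        frame["fdr"] = []
        frame["q_bh"] = []
        frame["significant"] = []
        return frame
    try:
        batch_fdr = fisher_chi2_fdr(
            frame["p_fisher"].to_numpy(), frame["p_chi2"].to_numpy()
        )
    except ValueError:
        batch_fdr = float("nan")  # chi2 undefined for every category
    frame["fdr"] = batch_fdr
    frame["q_bh"] = adjust_fdr_bh(frame["p_fisher"].to_numpy())
    frame["significant"] = frame["p_fisher"] < p_threshold
    frame = frame.sort_values(
        ["p_fisher", "re", "category"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return frame
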