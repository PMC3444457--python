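"""Significant temporal-pattern clustering (STC).

Differentially expressed genes are assigned to predefined discretised
time-course templates — all sequences of unit up/flat/down transitions,
cumulated from zero — by maximal Pearson correlation between each gene's
0 h-anchored mean profile and the piecewise-linear template.  Template
significance is assessed by permutation: time labels are permuted
independently per gene, genes are reassigned, and a template's p-value is
the (add-one smoothed) fraction of permutations whose count reaches the
observed count.  The number of "significant" templates is a result of the
data, not a parameter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix


@dataclass
class STCProfileSet:
    """Temporal templates plus (after assignment/testing) their statistics."""

    transitions: np.ndarray  # (K, T-1) ints in [-cap, cap]
    templates: np.ndarray  # (K, T) floats, cumulated from 0
    max_unit_change: int
    flat_index: int
    assignments: pd.DataFrame | None = None  # gene_id, template_id, correlation
    profiles: pd.DataFrame | None = None  # anchored gene profiles (genes x T)
    stats: pd.DataFrame | None = None  # template_id, transitions, observed, expected, p_value

    @property
    def n_templates(self) -> int:
        return self.templates.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.templates.shape[1]

    def transition_string(self, template_id: int) -> str:
        return ",".join(f"{t:+d}" if t else "0" for t in self.transitions[template_id])


def build_profile_templates(n_timepoints: int, max_unit_change: int = 1) -> STCProfileSet:
    """Enumerate all discretised temporal templates.

    Each template is a sequence of T-1 transitions, each in
    {-max_unit_change, ..., +max_unit_change}, cumulated from 0 and rendered
    as a piecewise-linear profile of length T.  Ordering is lexicographic,
    so the template set (and tie-breaking) is deterministic; the flat
    profile is always present.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    cap = int(max_unit_change)
    if cap < 1:
        raise ValueError("max_unit_change must be >= 1")
    steps = range(-cap, cap + 1)
    transitions = np.array(
        list(itertools.product(steps, repeat=n_timepoints - 1)), dtype=int
    )
    templates = np.concatenate(
        [np.zeros((transitions.shape[0], 1)), np.cumsum(transitions, axis=1)], axis=1
    ).astype(float)
    flat_index = int(np.flatnonzero((transitions == 0).all(axis=1))[0])
    return STCProfileSet(transitions, templates, cap, flat_index)


def anchored_mean_profiles(
    matrix: ExpressionMatrix, genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene mean time course minus its 0 h (first time point) value."""
    means = matrix.mean_by_time()
    if genes is not None:
        means = means.loc[list(genes)]
    return means.sub(means.iloc[:, 0], axis=0)


def _assign(profiles: np.ndarray, pset: STCProfileSet) -> tuple[np.ndarray, np.ndarray]:
    """Max-correlation template index and correlation per gene profile.

    Zero-variance profiles go to the flat template with correlation 0; the
    flat template itself has no defined correlation and never wins argmax.
    Exact correlation ties resolve to the lowest template index via argmax.
    """
    T = pset.n_timepoints
    tpl = pset.templates - pset.templates.mean(axis=1, keepdims=True)
    tpl_norm = np.linalg.norm(tpl, axis=1)
    ok_tpl = tpl_norm > 0
    tplz = np.zeros_like(tpl)
    tplz[ok_tpl] = tpl[ok_tpl] / tpl_norm[ok_tpl][:, None]

    prof = profiles - profiles.mean(axis=1, keepdims=True)
    prof_norm = np.linalg.norm(prof, axis=1)
    flat_gene = prof_norm == 0
    profz = np.zeros_like(prof)
    profz[~flat_gene] = prof[~flat_gene] / prof_norm[~flat_gene][:, None]

    corr = profz @ tplz.T  # genes x templates
    corr[:, ~ok_tpl] = -2.0  # flat template never wins by correlation
    idx = np.argmax(corr, axis=1)
    best = corr[np.arange(len(idx)), idx]
    idx[flat_gene] = pset.flat_index
    best[flat_gene] = 0.0
    return idx, best


def assign_genes_to_profiles(
    log_ratio_profiles: pd.DataFrame, pset: STCProfileSet
) -> STCProfileSet:
    """Assign each gene to its best-correlated template.

    ``log_ratio_profiles`` holds per-gene anchored profiles (genes × T, first
    entry 0, see :func:`anchored_mean_profiles`).  Returns a new profile set
    carrying the assignments.
    """
    if log_ratio_profiles.shape[1] != pset.n_timepoints:
        raise ValueError(
            f"profiles have {log_ratio_profiles.shape[1]} time points, "
            f"templates have {pset.n_timepoints}"
        )
    idx, corr = _assign(log_ratio_profiles.to_numpy(dtype=float), pset)
    assignments = pd.DataFrame(
        {
            "gene_id": list(log_ratio_profiles.index),
            "template_id": idx,
            "correlation": corr,
        }
    )
    return STCProfileSet(
        pset.transitions,
        pset.templates,
        pset.max_unit_change,
        pset.flat_index,
        assignments=assignments,
        profiles=log_ratio_profiles.copy(),
    )


def profile_significance(
    pset: STCProfileSet, n_permutations: int = 1000, seed: int = 0
) -> STCProfileSet:
    """Permutation significance of per-template gene counts.

    Time labels are permuted independently per gene (Pearson correlation is
    location-invariant, so re-anchoring the permuted profile changes
    nothing), genes are reassigned, and for each template

        p = (1 + #{permutations with count >= observed}) / (n_permutations + 1).

    The expected count is the mean assigned count over permutations.
    """
    if pset.assignments is None or pset.profiles is None:
        raise ValueError("assign_genes_to_profiles must be run first")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    K = pset.n_templates
    observed = np.bincount(pset.assignments["template_id"].to_numpy(), minlength=K)
    prof = pset.profiles.to_numpy(dtype=float)

    exceed = np.zeros(K, dtype=int)
    total = np.zeros(K, dtype=float)
    for _ in range(n_permutations):
        perm = rng.permuted(prof, axis=1)
        idx, _ = _assign(perm, pset)
        counts = np.bincount(idx, minlength=K)
        exceed += counts >= observed
        total += counts
    p = (1.0 + exceed) / (n_permutations + 1.0)
    expected = total / n_permutations
    stats = pd.DataFrame(
        {
            "template_id": np.arange(K),
            "transitions": [pset.transition_string(k) for k in range(K)],
            "observed": observed,
            "expected": expected,
            "p_value": p,
        }
    )
    return STCProfileSet(
        pset.transitions,
        pset.templates,
        pset.max_unit_change,
        pset.flat_index,
        assignments=pset.assignments,
        profiles=pset.profiles,
        stats=stats,
    )


def significant_templates(
    pset: STCProfileSet, p_threshold: float = 0.05, top_k: int | None = None
) -> pd.DataFrame:
    """Templates with p < p_threshold (optionally only the top_k smallest p)."""
    if pset.stats is None:
        raise ValueError("profile_significance must be run first")
    sig = pset.stats[pset.stats["p_value"] < p_threshold]
    sig = sig.sort_values(["p_value", "template_id"]).reset_index(drop=True)
    if top_k is not None:
        sig = sig.head(top_k)
    return sig
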