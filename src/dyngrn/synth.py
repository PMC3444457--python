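"""Ground-truth networks and simulated expression datasets.

Every downstream stage of the pipeline is verified against data generated
here: a sparse signed CTRNN with designated hub genes drives a panel of
"dynamic" genes observed at the short irregular time design of a nerve-crush
study (0, 0.5, 1, 3, 6, 9 h, 3 replicates per time point), padded with null
genes whose mean profile is flat.  Matched gene-set and prior-interaction
annotations are generated with known planted enrichment and a controlled
catalog dropout, so that enrichment calls, edge provenance ("database"
vs "computed") and regulator ranking can all be checked against truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ctrnn import CTRNNModel, simulate_trajectories
from .datatypes import (
    ExpressionMatrix,
    GeneSetCollection,
    Interaction,
    InteractionCatalog,
)

#: The study's proximal-segment sampling design (hours).
DEFAULT_TIMEPOINTS = (0.0, 0.5, 1.0, 3.0, 6.0, 9.0)
DEFAULT_REPLICATES = 3

_MIN_HUB_OUT = 2


@dataclass
class GroundTruthNetwork:
    """A sparse signed CTRNN used as simulation ground truth."""

    gene_ids: list[str]
    W_true: np.ndarray  # (n, n), target x source
    tau_true: np.ndarray
    theta_true: np.ndarray
    hub_ids: list[str]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def true_edges(self) -> list[tuple[str, str, float]]:
        """(source, target, weight) for every nonzero off-diagonal entry."""
        out = []
        for i in range(self.n_genes):
            for j in range(self.n_genes):
                if i != j and self.W_true[i, j] != 0:
                    out.append((self.gene_ids[j], self.gene_ids[i], float(self.W_true[i, j])))
        return out

    def out_degrees(self) -> np.ndarray:
        off = self.W_true.copy()
        np.fill_diagonal(off, 0.0)
        return (off != 0).sum(axis=0)


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    truth: GroundTruthNetwork
    de_gene_ids: list[str]
    null_gene_ids: list[str]
    trajectories: pd.DataFrame | None = None  # noise-free network-gene means


def generate_ground_truth_network(
    n_genes: int,
    density: float,
    n_hubs: int,
    weight_scale: float = 1.0,
    seed: int = 0,
) -> GroundTruthNetwork:
    """Draw a sparse signed network with designated high-out-degree hubs.

    The number of nonzero off-diagonal weights equals
    ``round(density * n_genes * (n_genes - 1))``; hubs receive a boosted
    share of the outgoing edges so their out-degree strictly exceeds the
    median.  Nonzero weights are uniform on ±[0.5, 1] * weight_scale with
    balanced signs in expectation.  Deterministic for a fixed seed.
    """
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    if n_hubs >= n_genes:
        raise ValueError("n_hubs must be smaller than n_genes")
    n_edges = int(round(density * n_genes * (n_genes - 1)))
    if n_hubs > 0 and n_edges < n_hubs * _MIN_HUB_OUT:
        raise ValueError(
            f"density allows only {n_edges} edges, too few for {n_hubs} hubs"
        )
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    hubs = sorted(rng.choice(n_genes, size=n_hubs, replace=False).tolist()) if n_hubs else []

    W = np.zeros((n_genes, n_genes))
    pairs: list[tuple[int, int]] = []  # (target, source)
    if n_edges:
        # hubs take a boosted outgoing share, the rest is spread uniformly
        hub_deg = max(_MIN_HUB_OUT, int(np.ceil(3.0 * n_edges / n_genes)))
        hub_deg = min(hub_deg, n_genes - 1)
        for h in hubs:
            targets = rng.choice(
                [i for i in range(n_genes) if i != h],
                size=min(hub_deg, n_edges - len(pairs)),
                replace=False,
            )
            pairs.extend((int(t), h) for t in targets)
        remaining = n_edges - len(pairs)
        if remaining > 0:
            non_hub = [j for j in range(n_genes) if j not in hubs]
            candidates = [
                (i, j) for j in non_hub for i in range(n_genes) if i != j
            ]
            chosen = rng.choice(len(candidates), size=remaining, replace=False)
            pairs.extend(candidates[c] for c in chosen)
        mags = rng.uniform(0.5, 1.0, size=len(pairs)) * weight_scale
        signs = rng.choice([-1.0, 1.0], size=len(pairs))
        for (i, j), m, s in zip(pairs, mags, signs):
            W[i, j] = s * m

    tau = rng.uniform(0.5, 2.5, size=n_genes)
    theta = rng.uniform(-1.0, 1.0, size=n_genes)
    truth = GroundTruthNetwork(
        gene_ids, W, tau, theta, hub_ids=[gene_ids[h] for h in hubs]
    )
    deg = truth.out_degrees()
    if n_hubs and not all(deg[h] > np.median(deg) for h in hubs):
        raise AssertionError("hub construction failed to exceed the median out-degree")
    return truth


def simulate_dataset(
    truth: GroundTruthNetwork,
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS,
    replicates: int = DEFAULT_REPLICATES,
    noise_sd: float = 0.1,
    n_null_genes: int = 150,
    seed: int = 0,
    step: float = 0.025,
) -> SyntheticDataset:
    """Simulate a replicated time-course dataset from a ground-truth CTRNN.

    Network genes follow numerically integrated CTRNN trajectories from
    initial states uniform on (0.2, 0.8) — the sigmoid's responsive range.
    Null genes have constant means drawn from the empirical range of the
    network trajectories, so differential-expression selection must work by
    temporal variation, not absolute level.  Independent Gaussian noise of
    sd ``noise_sd`` is added to every replicate measurement.
    """
    times = tuple(float(t) for t in timepoints)
    if len(times) < 3 or any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("timepoints must be sorted with at least 3 points")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = truth.n_genes

    model = CTRNNModel(truth.gene_ids, truth.W_true, truth.tau_true, truth.theta_true)
    g0 = rng.uniform(0.2, 0.8, size=n)
    traj = simulate_trajectories(model, g0, times, step=step)  # n x T

    null_ids = [f"N{i:04d}" for i in range(n_null_genes)]
    lo, hi = float(traj.min()), float(traj.max())
    if hi <= lo:
        lo, hi = lo - 0.5, hi + 0.5
    null_means = rng.uniform(lo, hi, size=n_null_genes)

    sample_names = []
    design_rows = []
    columns = []
    for t in times:
        for r in range(1, replicates + 1):
            name = f"t{t:g}_r{r}"
            sample_names.append(name)
            design_rows.append((name, t, r))
    mean_matrix = np.empty((n + n_null_genes, len(sample_names)))
    for col, (_, t, _) in enumerate(design_rows):
        ti = times.index(t)
        mean_matrix[:n, col] = traj[:, ti]
        mean_matrix[n:, col] = null_means
    noise = rng.normal(0.0, noise_sd, size=mean_matrix.shape) if noise_sd > 0 else 0.0
    values = pd.DataFrame(
        mean_matrix + noise, index=truth.gene_ids + null_ids, columns=sample_names
    )
    design = pd.DataFrame(
        design_rows, columns=["sample", "time_hours", "replicate"]
    ).set_index("sample")
    em = ExpressionMatrix(values, design)
    return SyntheticDataset(
        expression=em,
        truth=truth,
        de_gene_ids=list(truth.gene_ids),
        null_gene_ids=null_ids,
        trajectories=pd.DataFrame(traj, index=truth.gene_ids, columns=list(times)),
    )


def generate_annotations(
    dataset: SyntheticDataset,
    n_categories: int = 30,
    enriched_categories: int = 5,
    dropout: float = 0.3,
    category_size: int = 15,
    seed: int = 0,
) -> tuple[GeneSetCollection, InteractionCatalog]:
    """Gene sets with planted enrichment, and a prior catalog with dropout.

    Enriched categories draw >= 80% of their members from the dynamic
    (network-driven) genes and jointly cover all of them (dynamic genes are
    dealt round-robin across the enriched categories before topping up),
    mirroring how a pathway-built network only contains pathway-annotated
    genes; background categories sample all genes uniformly.  The catalog
    contains each true edge with probability ``1 - dropout`` (type from the
    weight sign), so a known fraction of true edges must be rediscovered as
    "computed".
    """
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    if enriched_categories > n_categories:
        raise ValueError("enriched_categories must be <= n_categories")
    if not 0 <= dropout <= 1:
        raise ValueError("dropout must be in [0, 1]")
    rng = np.random.default_rng(seed)
    de = list(dataset.de_gene_ids)
    all_genes = list(dataset.expression.gene_ids)

    # deal dynamic genes round-robin so the enriched categories cover them all
    dealt: list[set[str]] = [set() for _ in range(enriched_categories)]
    if enriched_categories and de:
        order = rng.permutation(len(de))
        for k, gi in enumerate(order):
            dealt[k % enriched_categories].add(de[gi])

    categories: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for c in range(n_categories):
        name = f"CAT{c:03d}"
        if c < enriched_categories:
            n_de = int(np.ceil(0.9 * category_size))
            n_bg = category_size - n_de
            members = set(dealt[c])
            pool = [g for g in de if g not in members]
            if len(members) < n_de and pool:
                extra = rng.choice(pool, size=min(n_de - len(members), len(pool)), replace=False)
                members |= set(extra)
            others = [g for g in all_genes if g not in members and g not in de]
            if n_bg and others:
                members |= set(rng.choice(others, size=min(n_bg, len(others)), replace=False))
            descriptions[name] = "planted enriched category"
        else:
            members = set(
                rng.choice(all_genes, size=min(category_size, len(all_genes)), replace=False)
            )
            descriptions[name] = "background category"
        categories[name] = frozenset(members)
    sets = GeneSetCollection(categories, descriptions)

    records = []
    for source, target, w in dataset.truth.true_edges():
        if rng.random() < 1.0 - dropout:
            itype = "activation" if w > 0 else "inhibition"
            records.append(Interaction(source, target, itype))
    return sets, InteractionCatalog(records)
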