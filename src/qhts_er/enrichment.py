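"""Structure-class clustering and per-cluster activity enrichment.

The library's binary fingerprints are clustered with a self-organizing map
(batch algorithm: Gaussian neighborhood on a rectangular grid with an
exponentially shrinking radius, codebook updated as the
neighborhood-weighted mean of the assigned fingerprints). Compounds are
assigned to their nearest node, ties broken toward the lowest node index;
occupied nodes play the role of structural clusters. The default
assignment distance is squared Euclidean against the continuous codebook
(for 0/1 fingerprints this is a soft Hamming distance that retains the
prototype's bit frequencies); 'hamming' and 'tanimoto' against the
codebook thresholded at 0.5 are available, but binarization collapses
nearly-tied prototypes onto identical bit patterns and can split one tight
structural family across two nodes on noise bits alone.

Each node is then tested for enrichment of an activity category with the
two-sided Fisher exact test on the (in-cluster vs out) x (in-category vs
not) table. Antagonist-enriched nodes that are simultaneously enriched in
cytotoxicity-demoted antagonist calls are flagged as confounded and
excluded from the reported enriched set, since concurrent cytotoxicity, not
receptor antagonism, is the parsimonious explanation for those clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assays import MODE_ASSAYS, mode_of
from .evaluation import fisher_exact_2x2

#: the call that counts as "active" for each endpoint's enrichment test
ACTIVE_CATEGORY = {
    "agonist": "active_agonist",
    "antagonist": "active_antagonist",
}
CYTOTOX_CATEGORY = "inconclusive_antagonist_cytotox"


@dataclass
class SOMModel:
    rows: int
    cols: int
    codebook: np.ndarray  # (rows * cols, n_bits), values in [0, 1]
    epochs: int
    seed: int

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def assign(self, fingerprints: np.ndarray, metric: str = "euclidean") -> np.ndarray:
        """Nearest node per compound; ties break toward the lowest index.

        metric 'euclidean' compares against the continuous codebook;
        'hamming' and 'tanimoto' against the codebook thresholded at 0.5.
        """
        fp = np.asarray(fingerprints, dtype=float)
        if metric == "euclidean":
            d = (
                (fp**2).sum(axis=1, keepdims=True)
                + (self.codebook**2).sum(axis=1)[None, :]
                - 2 * fp @ self.codebook.T
            )
        elif metric == "hamming":
            book = (self.codebook >= 0.5).astype(float)
            # Hamming distance = popcount of XOR, via the matmul identity
            d = (
                fp.sum(axis=1, keepdims=True)
                + book.sum(axis=1)[None, :]
                - 2 * (fp @ book.T)
            )
        elif metric == "tanimoto":
            book = (self.codebook >= 0.5).astype(float)
            inter = fp @ book.T
            union = fp.sum(axis=1, keepdims=True) + book.sum(axis=1)[None, :] - inter
            with np.errstate(invalid="ignore"):
                d = 1.0 - np.where(union > 0, inter / union, 1.0)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        return np.argmin(d, axis=1)


def default_grid(n_compounds: int, compounds_per_cluster: float = 13.0) -> tuple[int, int]:
    """Square grid sized so clusters hold ~13 compounds on average."""
    side = max(2, int(round(np.sqrt(n_compounds / compounds_per_cluster))))
    return side, side


def train_som(
    fingerprints: np.ndarray,
    rows: int | None = None,
    cols: int | None = None,
    epochs: int = 24,
    sigma_end: float = 0.5,
    seed: int = 0,
    compounds_per_cluster: float = 13.0,
    metric: str = "euclidean",
) -> tuple[SOMModel, np.ndarray]:
    """Train a batch SOM on binary fingerprints; returns (model, assignments)."""
    fp = np.asarray(fingerprints, dtype=float)
    if fp.ndim != 2 or fp.shape[0] == 0:
        raise ValueError("fingerprints must be a non-empty 2-D array")
    n, bits = fp.shape
    if rows is None or cols is None:
        rows, cols = default_grid(n, compounds_per_cluster)
    if rows < 1 or cols < 1:
        raise ValueError("grid must be at least 1x1")
    n_nodes = rows * cols
    rng = np.random.default_rng(seed)

    # farthest-point initialization: seeds the codebook with mutually
    # distant fingerprints so no two nodes start inside one structural
    # family (random restarts of dense regions cause cluster splitting)
    init_idx = [int(rng.integers(0, n))]
    d_min = np.abs(fp - fp[init_idx[0]]).sum(axis=1)
    while len(init_idx) < min(n_nodes, n):
        nxt = int(np.argmax(d_min))
        init_idx.append(nxt)
        d_min = np.minimum(d_min, np.abs(fp - fp[nxt]).sum(axis=1))
    while len(init_idx) < n_nodes:  # tiny libraries: recycle samples
        init_idx.append(init_idx[len(init_idx) % n])
    codebook = fp[np.array(init_idx)] * 0.8 + 0.1
    codebook = codebook + rng.normal(0, 0.02, (n_nodes, bits))
    codebook = np.clip(codebook, 0.0, 1.0)

    grid_pos = np.array([(r, c) for r in range(rows) for c in range(cols)], float)
    grid_d2 = ((grid_pos[:, None, :] - grid_pos[None, :, :]) ** 2).sum(-1)

    sigma0 = max(rows, cols) / 2.0
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        sigma = sigma0 * (sigma_end / sigma0) ** frac
        d = ((fp**2).sum(1, keepdims=True)
             + (codebook**2).sum(1)[None, :]
             - 2 * fp @ codebook.T)
        bmu = np.argmin(d, axis=1)
        h = np.exp(-grid_d2 / (2.0 * sigma**2))  # (nodes, nodes)
        w = h[:, bmu]                            # (nodes, n) weights per sample
        denom = w.sum(axis=1, keepdims=True)
        nonzero = denom[:, 0] > 1e-12
        codebook[nonzero] = (w @ fp)[nonzero] / denom[nonzero]

    model = SOMModel(rows=rows, cols=cols, codebook=codebook, epochs=epochs, seed=seed)
    return model, model.assign(fingerprints, metric=metric)


# --------------------------------------------------------------------------
# enrichment
# --------------------------------------------------------------------------

def cluster_enrichment(
    assignments: np.ndarray,
    in_category: np.ndarray,
    n_nodes: int,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-node Fisher enrichment of one activity category.

    Returns a table with in/out counts, the two-sided p, the enriched flag
    (p < threshold and over-represented) and a signed log10 p (positive =
    over-represented) for heatmap export.
    """
    assignments = np.asarray(assignments)
    in_category = np.asarray(in_category, dtype=bool)
    if len(assignments) != len(in_category):
        raise ValueError("assignments and category mask differ in length")
    total, total_cat = len(assignments), int(in_category.sum())
    rows = []
    for node in range(n_nodes):
        mask = assignments == node
        size, k = int(mask.sum()), int(in_category[mask].sum())
        a, b = k, size - k
        c, d = total_cat - k, (total - size) - (total_cat - k)
        p = fisher_exact_2x2(a, b, c, d) if size else 1.0
        rate_in = k / size if size else 0.0
        rate_out = (total_cat - k) / (total - size) if total > size else 0.0
        over = rate_in > rate_out
        signed = -np.log10(max(p, 1e-300)) * (1.0 if over else -1.0)
        rows.append({
            "cluster_id": node, "size": size, "n_category": k,
            "n_category_background": total_cat - k, "p": p,
            "enriched": bool(p < p_threshold and over),
            "signed_log10_p": float(signed),
        })
    return pd.DataFrame(rows)


def endpoint_enrichment(
    assignments: np.ndarray,
    calls: pd.DataFrame,
    compound_ids: list[str],
    n_nodes: int,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Enrichment of every mode assay's active category over all nodes,
    with the cytotoxicity-confound flag on antagonist endpoints."""
    frames = []
    for assay_id in MODE_ASSAYS:
        sub = calls[
            (calls["assay_id"] == assay_id) & calls["compound_id"].isin(compound_ids)
        ]
        outcome = pd.Series("", index=compound_ids, dtype=object)
        outcome.loc[sub["compound_id"]] = sub["outcome"].to_numpy()
        active = (outcome == ACTIVE_CATEGORY[mode_of(assay_id)]).to_numpy()
        enr = cluster_enrichment(assignments, active, n_nodes, p_threshold)
        enr.insert(0, "assay_id", assay_id)
        if mode_of(assay_id) == "antagonist":
            cyto = (outcome == CYTOTOX_CATEGORY).to_numpy()
            cyto_enr = cluster_enrichment(assignments, cyto, n_nodes, p_threshold)
            enr["confounded"] = enr["enriched"] & cyto_enr["enriched"]
        else:
            enr["confounded"] = False
        enr["reported_enriched"] = enr["enriched"] & ~enr["confounded"]
        frames.append(enr)
    return pd.concat(frames, ignore_index=True)


def enrichment_matrix(endpoint_table: pd.DataFrame) -> pd.DataFrame:
    """Node x endpoint matrix of signed log10 p (heatmap-ready)."""
    return endpoint_table.pivot(
        index="cluster_id", columns="assay_id", values="signed_log10_p"
    )
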