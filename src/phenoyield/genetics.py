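"""Genetic structure and genotype-stratified cross-validation.

Reduces a varieties x markers matrix (0/1/2 allele dosages) by PCA, picks a
component count with the elbow rule, clusters varieties by k-means, excludes
check plots, and builds cluster-stratified 5-fold assignments with a
train/validation split inside each fold.

The fold protocol is 80/20 train+val/test per fold and a 90/10 train/
validation split of the non-test plots, every split stratified by cluster
label through largest-remainder allocation with seeded tie-breaks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticPCAResult",
    "FoldAssignment",
    "pca_markers",
    "elbow_select",
    "kmeans_cluster",
    "exclude_checks",
    "stratified_folds",
]


@dataclass
class GeneticPCAResult:
    scores: np.ndarray                     # varieties x components
    explained_variance_fraction: np.ndarray
    n_selected: int | None = None

    def select(self) -> "GeneticPCAResult":
        """Apply the elbow rule and record the selected component count."""
        self.n_selected = elbow_select(self.explained_variance_fraction)
        return self

    def save_diagnostics(self, path) -> None:
        """Write explained-variance diagnostics as JSON."""
        import json
        from pathlib import Path

        payload = {
            "explained_variance_fraction": self.explained_variance_fraction.tolist(),
            "n_selected": self.n_selected,
            "n_components": int(self.scores.shape[1]),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class FoldAssignment:
    """Plot-level fold membership and per-fold train/val/test roles.

    `table` has one row per (plot, fold) with columns plot_id, fold, role in
    {train, validation, test}; `test_fold` maps each plot to the single fold
    where it is tested.
    """

    table: pd.DataFrame
    n_folds: int

    def ids(self, fold: int, role: str) -> np.ndarray:
        t = self.table
        return t.loc[(t["fold"] == fold) & (t["role"] == role), "plot_id"].to_numpy()

    @property
    def test_fold(self) -> dict:
        t = self.table
        return dict(
            zip(t.loc[t["role"] == "test", "plot_id"], t.loc[t["role"] == "test", "fold"])
        )

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def pca_markers(
    marker_matrix: np.ndarray, n_components: int, scale: bool = False
) -> GeneticPCAResult:
    """PCA of the (varieties x markers) dosage matrix.

    Markers are centered; variance-scaling is off by default since dosages
    share a scale.  Explained-variance fractions are relative to the total
    variance of the (possibly scaled) matrix.
    """
    X = np.asarray(marker_matrix, dtype=float)
    if X.shape[0] < 2:
        raise DomainError("PCA needs at least two varieties")
    if n_components > min(X.shape):
        raise DomainError("n_components exceeds matrix rank bound")
    if scale:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return GeneticPCAResult(scores, pca.explained_variance_ratio_.copy())


def elbow_select(explained_variance_fractions: np.ndarray, tol: float = 1e-3) -> int:
    """Component count at the scree elbow.

    The scree curve is normalised to the unit square and the elbow is the
    point with maximum perpendicular distance to the chord joining the first
    and last points.  The components *preceding* the elbow point are
    retained: on the L-shaped screes cluster-structured marker data produce,
    the elbow point itself is the first noise component.  A flat or
    near-linear scree has no elbow; 1 is returned with a warning.
    """
    ev = np.asarray(explained_variance_fractions, dtype=float)
    if ev.size < 3:
        raise DomainError("elbow selection needs >= 3 components")
    x = np.linspace(0.0, 1.0, ev.size)
    rng_y = ev[0] - ev[-1]
    if rng_y == 0:
        warnings.warn("flat scree: no elbow, selecting 1 component")
        return 1
    y = (ev - ev[-1]) / rng_y
    # distance from (x_i, y_i) to the line through (0, 1) and (1, 0)
    dist = np.abs(x + y - 1.0) / np.sqrt(2.0)
    if dist.max() < tol:
        warnings.warn("near-linear scree: no elbow, selecting 1 component")
        return 1
    return max(1, int(np.argmax(dist)))


def kmeans_cluster(
    scores: np.ndarray, k: int, seed: int, n_restarts: int = 10
) -> np.ndarray:
    """k-means labels on PCA scores; best of `n_restarts` seeded restarts."""
    scores = np.asarray(scores, dtype=float)
    if k < 1:
        raise DomainError("k must be >= 1")
    if k > scores.shape[0]:
        raise DomainError("k exceeds the number of points")
    if k == 1:
        return np.zeros(scores.shape[0], dtype=int)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(scores)


def exclude_checks(plot_table: pd.DataFrame) -> pd.DataFrame:
    """Drop check plots (is_check == True); the removed count is logged."""
    n_checks = int(plot_table["is_check"].sum())
    out = plot_table.loc[~plot_table["is_check"].astype(bool)].reset_index(drop=True)
    logger.info("excluded %d check plots, %d retained", n_checks, len(out))
    if out.empty:
        warnings.warn("all plots are checks: empty table after exclusion")
    return out


def _largest_remainder_counts(n: int, shares: np.ndarray, rng) -> np.ndarray:
    """Integer allocation of n items proportional to `shares` (sum to 1)."""
    exact = n * shares
    base = np.floor(exact).astype(int)
    short = n - base.sum()
    frac = exact - base
    # ties broken by seeded shuffle
    order = rng.permutation(len(shares))
    ranked = order[np.argsort(-frac[order], kind="stable")]
    base[ranked[:short]] += 1
    return base


def stratified_folds(
    plot_table: pd.DataFrame,
    n_folds: int = 5,
    val_fraction: float = 0.10,
    seed: int = 0,
) -> FoldAssignment:
    """Cluster-stratified k-fold assignment with inner train/val splits.

    `plot_table` needs columns plot_id and cluster.  Every plot is tested in
    exactly one fold; within each fold the non-test plots are split
    (1 - val_fraction)/val_fraction into train/validation, again per cluster.
    """
    rng = np.random.default_rng(seed)
    plots = plot_table[["plot_id", "cluster"]].reset_index(drop=True)
    clusters = np.sort(plots["cluster"].unique())

    fold_of = {}
    for c in clusters:
        members = plots.loc[plots["cluster"] == c, "plot_id"].to_numpy()
        if len(members) < n_folds:
            warnings.warn(
                f"cluster {c} has fewer members ({len(members)}) than folds"
            )
        members = rng.permutation(members)
        counts = _largest_remainder_counts(
            len(members), np.full(n_folds, 1.0 / n_folds), rng
        )
        idx = 0
        for fold, cnt in enumerate(counts):
            for pid in members[idx : idx + cnt]:
                fold_of[pid] = fold
            idx += cnt

    rows = []
    for fold in range(n_folds):
        test_ids = {pid for pid, f in fold_of.items() if f == fold}
        rest = plots.loc[~plots["plot_id"].isin(test_ids)]
        val_ids = set()
        # validation quota per cluster, largest remainder across clusters
        quotas = {}
        for c in clusters:
            members = rest.loc[rest["cluster"] == c, "plot_id"].to_numpy()
            quotas[c] = val_fraction * len(members)
        n_val = int(round(sum(quotas.values())))
        base = {c: int(np.floor(q)) for c, q in quotas.items()}
        frac_order = sorted(
            clusters, key=lambda c: -(quotas[c] - base[c])
        )
        short = n_val - sum(base.values())
        for c in frac_order[:short]:
            base[c] += 1
        for c in clusters:
            members = rest.loc[rest["cluster"] == c, "plot_id"].to_numpy()
            members = rng.permutation(members)
            val_ids.update(members[: base[c]])
        for pid in plots["plot_id"]:
            if pid in test_ids:
                role = "test"
            elif pid in val_ids:
                role = "validation"
            else:
                role = "train"
            rows.append({"plot_id": pid, "fold": fold, "role": role})

    return FoldAssignment(pd.DataFrame(rows), n_folds)
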