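"""Clustering of ASHM sites by per-modification imbalance profiles.

Each significant site is summarised as a signed vector over
modifications: magnitude -log10 of the per-modification binomial
p-value, sign indicating which allele the modification favors.  The
sign anchor is per-site (the allele favored by the site's most
significant modification), so profiles are only defined up to a global
flip — the similarity used, squared Pearson correlation, is flip
invariant.  Sites are clustered agglomeratively on distance 1 - r^2
(average linkage); the dendrogram is cut by progressively lowering the
height until further lowering would split sites driven by the same
modifications into multiple clusters, and each cluster's driver
modifications are those with small binomial p-values on a consistent
allele side across most of its sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: cap on -log10 p to keep profile entries finite and comparable
MAX_NEG_LOG10_P = 300.0


def build_imbalance_profiles(per_modification: pd.DataFrame,
                             modifications: tuple[str, ...]
                             ) -> pd.DataFrame:
    """Signed -log10 binomial p profiles, one row per site.

    The positive direction at each site is the allele favored by the
    site's most significant modification (ties broken by the column
    order of ``modifications``); untested modifications (p = 1, no
    favored allele) contribute zero.
    """
    prof = pd.DataFrame(0.0, index=pd.Index(
        per_modification["site_id"].unique(), name="site_id"),
        columns=list(modifications))
    for site_id, grp in per_modification.groupby("site_id", sort=False):
        grp = grp.set_index("modification").reindex(list(modifications))
        logp = -np.log10(grp["binomial_p"].fillna(1.0).clip(
            lower=10.0 ** -MAX_NEG_LOG10_P))
        favored = grp["favored_allele"]
        with_signal = logp[(logp > 0) & favored.notna()]
        if with_signal.empty:
            continue
        anchor_mod = with_signal.idxmax()
        anchor_allele = favored[anchor_mod]
        sign = pd.Series(0.0, index=grp.index)
        sign[favored == anchor_allele] = 1.0
        sign[favored.notna() & (favored != anchor_allele)] = -1.0
        prof.loc[site_id] = (sign * logp).to_numpy()
    return prof


def _squared_correlation(profiles: np.ndarray) -> np.ndarray:
    """Pairwise r^2 across modifications; zero-variance rows get r = 0."""
    sd = profiles.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d constant profile(s): correlations set to 0",
                       int(degenerate.sum()))
    safe = profiles.copy()
    safe[degenerate] = 0.0
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(safe)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    return r ** 2


@dataclass
class ClusterResult:
    """Dendrogram, per-site labels and per-cluster driver tables."""

    site_ids: list[str]
    linkage_matrix: np.ndarray
    labels: np.ndarray
    cut_height: float
    drivers: dict[int, frozenset[tuple[str, int]]] = field(
        default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def driver_table(self) -> pd.DataFrame:
        """Drivers as allele-A / allele-B modification lists per cluster."""
        rows = []
        for cluster, drv in sorted(self.drivers.items()):
            side_a = sorted(m for m, s in drv if s > 0)
            side_b = sorted(m for m, s in drv if s < 0)
            rows.append({"cluster": cluster,
                         "allele_a_modifications": ",".join(side_a),
                         "allele_b_modifications": ",".join(side_b),
                         "n_sites": int((self.labels == cluster).sum())})
        return pd.DataFrame(rows)


def cluster_sites(profiles: pd.DataFrame) -> ClusterResult:
    """Average-linkage hierarchy on distance 1 - r^2 between profiles.

    Sites are ordered by identifier for deterministic tie-breaking.
    """
    if len(profiles) < 2:
        raise ValueError("clustering needs at least 2 profiles")
    profiles = profiles.sort_index()
    r2 = _squared_correlation(profiles.to_numpy())
    dist = 1.0 - r2
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    return ClusterResult(site_ids=list(profiles.index), linkage_matrix=z,
                         labels=np.ones(len(profiles), dtype=int),
                         cut_height=float("inf"))


def _align_signs(block: np.ndarray) -> np.ndarray:
    """Flip member profiles to agree with the strongest member.

    r^2 clustering is blind to per-site sign flips, so members of one
    cluster may anchor opposite alleles; driver calling needs a common
    orientation.
    """
    ref = block[np.argmax(np.abs(block).sum(axis=1))]
    flips = np.sign(block @ ref)
    flips[flips == 0] = 1.0
    return block * flips[:, None]


def _cluster_drivers(block: np.ndarray, modifications,
                     driver_p_threshold: float
                     ) -> frozenset[tuple[str, int]]:
    """Modifications significant on a consistent side in >= half the sites."""
    aligned = _align_signs(block)
    cut = -np.log10(driver_p_threshold)
    need = -(-len(aligned) // 2)   # ceil(n/2)
    drivers = {}
    for j, mod in enumerate(modifications):
        col = aligned[:, j]
        n_pos = int((col > cut).sum())
        n_neg = int((col < -cut).sum())
        if max(n_pos, n_neg) >= need:
            drivers[mod] = 1 if n_pos >= n_neg else -1
    if not drivers:
        return frozenset()
    # canonical up to a global sign flip: which allele is "A" at a site
    # is arbitrary, so a pattern and its mirror are the same driver set
    plain = tuple(sorted((m, s) for m, s in drivers.items()))
    flipped = tuple(sorted((m, -s) for m, s in drivers.items()))
    # prefer the orientation that puts drivers on the positive (allele A)
    # side first, deterministically
    return frozenset(min(plain, flipped,
                         key=lambda t: tuple((m, -s) for m, s in t)))


def choose_cut_and_drivers(result: ClusterResult, profiles: pd.DataFrame,
                           driver_p_threshold: float = 0.01
                           ) -> ClusterResult:
    """Cut the dendrogram as low as driver distinctness allows.

    Candidate cut heights descend through the merge heights; at each cut
    every cluster's driver set is computed, and the chosen cut is the
    lowest at which all driver sets are pairwise distinct.  If even the
    two-cluster cut repeats a driver set, a single cluster is returned
    with a warning.
    """
    profiles = profiles.sort_index()
    assert list(profiles.index) == result.site_ids
    mat = profiles.to_numpy()
    modifications = tuple(profiles.columns)
    heights = np.unique(result.linkage_matrix[:, 2])
    cuts = sorted(set(np.concatenate([heights * 0.999, [heights[-1] * 1.001]])),
                  reverse=True)
    best_labels = np.ones(len(mat), dtype=int)
    best_cut = float(cuts[0])
    best_drivers = {1: _cluster_drivers(mat, modifications,
                                        driver_p_threshold)}
    found = False
    for cut in cuts:
        labels = fcluster(result.linkage_matrix, t=cut,
                          criterion="distance")
        drivers = {c: _cluster_drivers(mat[labels == c], modifications,
                                       driver_p_threshold)
                   for c in np.unique(labels)}
        sets = list(drivers.values())
        if len(set(sets)) < len(sets):
            break    # lowering further repeats a driver set: stop above
        best_labels, best_cut, best_drivers = labels, float(cut), drivers
        found = True
    if not found:
        logger.warning("no cut separates clusters by distinct drivers; "
                       "returning a single cluster")
    return ClusterResult(site_ids=result.site_ids,
                         linkage_matrix=result.linkage_matrix,
                         labels=best_labels, cut_height=best_cut,
                         drivers=best_drivers)


def serialize_dendrogram(result: ClusterResult) -> str:
    """Nested-parenthesis text form of the dendrogram (leaf = site id)."""
    n = len(result.site_ids)
    nodes: dict[int, str] = {i: result.site_ids[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(result.linkage_matrix):
        nodes[n + k] = f"({nodes[int(a)]},{nodes[int(b)]}):{h:.6g}"
    return nodes[n + len(result.linkage_matrix) - 1] if n > 1 else nodes[0]
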