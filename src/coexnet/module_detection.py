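"""Module detection: clustering, adaptive tree cut, eigengenes, merging.

Features are hierarchically clustered (average linkage) on the TOM
dissimilarity, and modules are read off the dendrogram with an adaptive
branch cut rather than a single static height. The cut implemented here
is the package's normative algorithm:

1. Merges are replayed bottom-up (heights are non-decreasing in average
   linkage). Merges above ``cut_height`` (default 0.99 of the top merge
   height) are never applied.
2. A growing branch records, for every member, the height at which it
   joined. Heights are normalized to [0, 1] between the 5th percentile
   of merge heights and ``cut_height``.
3. When two branches meet, each is asked whether it is a *bona fide
   cluster* at its attachment height h: it must have at least
   ``min_module_size`` members, its core scatter (mean normalized
   joining height of its lowest-joining ``min_module_size`` members)
   must not exceed ``max_core_scatter``, and the gap between h and its
   highest internal merge must be at least ``min_gap``. If both sides
   qualify they are committed as separate modules; otherwise they
   coalesce into one branch (a branch meeting an already-committed
   composite without qualifying dissolves into unassigned features).
   Branches still separate when the replay reaches ``cut_height`` are
   evaluated on size and core scatter only — the static cut itself
   already separates them, so the gap test is waived.
4. ``deep_split`` in 0..4 controls sensitivity by interpolating
   ``max_core_scatter`` over (0.64, 0.73, 0.82, 0.91, 0.95) with
   ``min_gap = (1 - max_core_scatter) * 3/4`` — higher values split
   more aggressively.
5. Each final module is trimmed: members whose joining height exceeds
   median + 3 * 1.4826 * MAD of the module's joining heights are set
   back to unassigned (outlying late attachments).
6. With ``pam_stage`` on, each unassigned feature is assigned to the
   module with the smallest average dissimilarity, but only when that
   average is strictly smaller than the feature's average
   dissimilarity to all other features (joining must beat staying
   unassigned) and no larger than the module's own radius (largest
   member-to-co-members average dissimilarity), which keeps
   noise features equidistant from everything unassigned.

Modules are labelled 1..M by decreasing size; 0 is the unassigned
("grey") label. Each module is summarized by its eigengene: the first
principal component of the standardized module submatrix, scaled to
unit variance across samples and sign-oriented to correlate
non-negatively with the module's mean standardized expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from coexnet.core_data import ExpressionDataset

logger = logging.getLogger(__name__)

# conventional module color sequence; 0/"grey" is reserved for unassigned
_COLOR_SEQUENCE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta", "coral",
]

_CORE_SCATTER_BY_DEEPSPLIT = (0.64, 0.73, 0.82, 0.91, 0.95)


def _color_name(label: int) -> str:
    if label == 0:
        return "grey"
    if label <= len(_COLOR_SEQUENCE):
        return _COLOR_SEQUENCE[label - 1]
    return f"module_{label}"


@dataclass
class ModuleAssignment:
    """Feature -> module label map (0 = unassigned/grey) with provenance."""

    labels: pd.Series  # index feature_id, int values
    dendrogram: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)

    @property
    def feature_ids(self) -> list[str]:
        return self.labels.index.tolist()

    @property
    def module_labels(self) -> list[int]:
        """Sorted labels of proper modules (excludes 0)."""
        return sorted(l for l in self.labels.unique() if l != 0)

    @property
    def n_modules(self) -> int:
        return len(self.module_labels)

    @property
    def color_names(self) -> dict[int, str]:
        return {int(l): _color_name(int(l)) for l in sorted(self.labels.unique())}

    def module_sizes(self) -> dict[int, int]:
        counts = self.labels.value_counts()
        return {int(l): int(counts[l]) for l in sorted(counts.index)}

    def features_in(self, label: int) -> list[str]:
        return self.labels.index[self.labels == label].tolist()

    def as_sets(self, include_unassigned: bool = True) -> dict[str, set[str]]:
        """Module color -> gene set, for overlap comparisons."""
        out: dict[str, set[str]] = {}
        for label in sorted(self.labels.unique()):
            if label == 0 and not include_unassigned:
                continue
            out[_color_name(int(label))] = set(self.features_in(int(label)))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "module_label": self.labels.to_numpy(),
                "module_color": [_color_name(int(l)) for l in self.labels],
            },
            index=self.labels.index.rename("feature_id"),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ModuleAssignment":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=df["module_label"].astype(int))


@dataclass
class EigengeneSet:
    """Modules x samples eigengene matrix with variance explained."""

    eigengenes: pd.DataFrame  # index module label, columns sample ids
    variance_explained: pd.Series  # module label -> fraction
    orientation_sign: pd.Series  # module label -> +1 / -1

    @property
    def module_labels(self) -> list[int]:
        return [int(l) for l in self.eigengenes.index]

    @property
    def sample_ids(self) -> list[str]:
        return self.eigengenes.columns.tolist()

    def eigengene(self, label: int) -> np.ndarray:
        return self.eigengenes.loc[label].to_numpy()

    def to_tsv(self, path) -> None:
        self.eigengenes.to_csv(path, sep="\t", index_label="module_label")


# ---------------------------------------------------------------------------
# clustering and the adaptive tree cut
# ---------------------------------------------------------------------------

def _check_dissimilarity(diss: np.ndarray) -> np.ndarray:
    diss = np.asarray(diss, dtype=float)
    if diss.ndim != 2 or diss.shape[0] != diss.shape[1]:
        raise ValueError(f"dissimilarity must be square, got shape {diss.shape}")
    if not np.allclose(diss, diss.T, atol=1e-10, rtol=0.0):
        raise ValueError("dissimilarity must be symmetric")
    if np.any(np.abs(np.diag(diss)) > 1e-12):
        raise ValueError("dissimilarity must have a zero diagonal")
    if np.any(diss < 0):
        raise ValueError("dissimilarity must be non-negative")
    return diss


def cluster_features(diss: np.ndarray) -> np.ndarray:
    """Average-linkage merge tree over features (scipy linkage matrix)."""
    diss = _check_dissimilarity(diss)
    if diss.shape[0] < 2:
        raise ValueError("need at least 2 features to cluster")
    d = (diss + diss.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return linkage(squareform(d, checks=False), method="average")


class _Branch:
    """A growing dendrogram branch during the bottom-up replay."""

    __slots__ = ("members", "heights", "committed", "is_composite")

    def __init__(self) -> None:
        self.members: list[int] = []
        self.heights: list[float] = []
        self.committed: list[tuple[list[int], list[float]]] = []
        self.is_composite = False


def dynamic_tree_cut(
    dendrogram: np.ndarray,
    diss: np.ndarray,
    min_module_size: int = 30,
    deep_split: int = 2,
    pam_stage: bool = True,
    cut_height: float | None = None,
    feature_ids: list[str] | None = None,
) -> ModuleAssignment:
    """Adaptive branch cut of a feature dendrogram into modules.

    See the module docstring for the full algorithm. Branches smaller
    than ``min_module_size`` dissolve into label 0. If no branch
    qualifies (e.g. ``min_module_size`` exceeds the feature count) all
    features are unassigned, with a warning rather than an error.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be an integer in 0..4")
    diss = _check_dissimilarity(diss)
    n = diss.shape[0]
    Z = np.asarray(dendrogram, dtype=float)
    if Z.shape != (n - 1, 4):
        raise ValueError(
            f"dendrogram shape {Z.shape} inconsistent with {n} features"
        )
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n)]

    heights = Z[:, 2]
    if cut_height is None:
        cut_height = 0.99 * float(heights.max())
    ref = float(np.quantile(heights, 0.05))
    span = max(cut_height - ref, 1e-12)

    def hnorm(h: float) -> float:
        return min(max((h - ref) / span, 0.0), 1.0)

    max_core_scatter = float(_CORE_SCATTER_BY_DEEPSPLIT[int(deep_split)])
    min_gap = (1.0 - max_core_scatter) * 0.75

    def qualifies(b: _Branch, attach_height: float | None) -> bool:
        """attach_height None means the branch survived to the cut: the
        static cut already separates it, so the gap test is waived."""
        if b.is_composite:
            return True
        if len(b.members) < min_module_size:
            return False
        core = sorted(b.heights)[:min_module_size]
        core_scatter = float(np.mean([hnorm(h) for h in core]))
        if core_scatter > max_core_scatter:
            return False
        if attach_height is None:
            return True
        top_internal = hnorm(max(b.heights)) if b.heights else 0.0
        return hnorm(attach_height) - top_internal >= min_gap

    def as_committed(b: _Branch) -> list[tuple[list[int], list[float]]]:
        return b.committed if b.is_composite else [(b.members, b.heights)]

    # replay merges bottom-up
    branches: dict[int, _Branch] = {}

    def get(node: int, h: float) -> _Branch:
        if node < n:
            b = _Branch()
            b.members = [node]
            b.heights = [h]
            return b
        return branches.pop(node)

    floaters: list[int] = []
    for i in range(n - 1):
        h = float(Z[i, 2])
        if h > cut_height:
            break
        b1 = get(int(Z[i, 0]), h)
        b2 = get(int(Z[i, 1]), h)
        q1, q2 = qualifies(b1, h), qualifies(b2, h)
        merged = _Branch()
        if q1 and q2:
            merged.is_composite = True
            merged.committed = as_committed(b1) + as_committed(b2)
            merged.members = b1.members + b2.members
            merged.heights = b1.heights + b2.heights
        elif b1.is_composite or b2.is_composite:
            comp, other = (b1, b2) if b1.is_composite else (b2, b1)
            # a non-qualifying branch meeting a finished composite: its
            # features float free (PAM may still place them)
            floaters.extend(other.members)
            merged.is_composite = True
            merged.committed = comp.committed
            merged.members = comp.members
            merged.heights = comp.heights
        else:
            merged.members = b1.members + b2.members
            merged.heights = b1.heights + b2.heights
        branches[n + i] = merged

    clusters: list[tuple[list[int], list[float]]] = []
    for b in branches.values():
        if b.is_composite:
            clusters.extend(b.committed)
        elif qualifies(b, None):
            clusters.append((b.members, b.heights))
        else:
            floaters.extend(b.members)

    # trim outlying late attachments from each module
    labels = np.zeros(n, dtype=int)
    kept_clusters: list[list[int]] = []
    for members, hts in clusters:
        hts_arr = np.asarray(hts, dtype=float)
        med = float(np.median(hts_arr))
        mad = float(np.median(np.abs(hts_arr - med)))
        limit = med + 3.0 * 1.4826 * mad
        core_members = [m for m, hh in zip(members, hts_arr) if hh <= limit + 1e-12]
        if len(core_members) >= min_module_size:
            kept_clusters.append(core_members)
        # clusters trimmed below min size dissolve entirely

    if not kept_clusters:
        logger.warning(
            "no module met min_module_size=%d (n_features=%d); all features unassigned",
            min_module_size, n,
        )

    # label by decreasing size; ties by smallest first member index
    kept_clusters.sort(key=lambda ms: (-len(ms), min(ms)))
    for lab, members in enumerate(kept_clusters, start=1):
        labels[members] = lab

    if pam_stage and kept_clusters:
        labels = _pam_assign(labels, diss)

    # re-rank labels by final size (PAM can change sizes)
    labels = _relabel_by_size(labels)
    return ModuleAssignment(
        labels=pd.Series(labels, index=pd.Index(feature_ids, name="feature_id")),
        dendrogram=Z,
    )


def _pam_assign(labels: np.ndarray, diss: np.ndarray) -> np.ndarray:
    """Assign unassigned features to the nearest module when that beats
    staying unassigned.

    A feature joins the module with the smallest average dissimilarity
    only if (a) that average is strictly smaller than the feature's
    average dissimilarity to all other features, and (b) it is no
    larger than the module's radius — the largest average dissimilarity
    of any current member to its co-members. Condition (b) keeps
    features that are merely "least far" from every module (e.g. pure
    noise, equidistant from everything) unassigned.
    """
    labels = labels.copy()
    n = len(labels)
    module_labels = sorted(set(labels) - {0})
    unassigned = np.flatnonzero(labels == 0)
    if len(unassigned) == 0 or not module_labels:
        return labels
    member_idx = {m: np.flatnonzero(labels == m) for m in module_labels}
    radius = {}
    for m, idx in member_idx.items():
        sub = diss[np.ix_(idx, idx)]
        radius[m] = float((sub.sum(axis=1) / max(len(idx) - 1, 1)).max())
    for i in unassigned:
        overall = (diss[i].sum()) / max(n - 1, 1)  # avg to all other features
        best_m, best_d = 0, np.inf
        for m in module_labels:
            d = float(diss[i, member_idx[m]].mean())
            if d < best_d:
                best_m, best_d = m, d
        if best_d < overall - 1e-12 and best_d <= radius[best_m] + 1e-12:
            labels[i] = best_m
    return labels


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    module_labels = sorted(set(labels) - {0})
    if not module_labels:
        return labels
    order = sorted(
        module_labels,
        key=lambda m: (-int((labels == m).sum()), int(np.flatnonzero(labels == m)[0])),
    )
    remap = {old: new for new, old in enumerate(order, start=1)}
    remap[0] = 0
    return np.array([remap[l] for l in labels], dtype=int)


# ---------------------------------------------------------------------------
# eigengenes
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError(
            "constant feature in module; remove zero-variance features first"
        )
    return (X - mu) / sd


def compute_eigengenes(ds: ExpressionDataset, assignment: ModuleAssignment) -> EigengeneSet:
    """First-principal-component eigengene per module.

    Features are z-scored per feature; the eigengene is the leading left
    singular vector of the standardized samples x features submatrix,
    scaled to zero mean and unit variance across samples, and oriented
    so it correlates non-negatively with the module's mean standardized
    expression. variance_explained is the leading eigenvalue's share of
    total variance in the module.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples for eigengenes")
    ds.require_complete("eigengene computation")
    missing = set(assignment.feature_ids) - set(ds.feature_ids)
    if missing:
        raise ValueError(f"assignment features absent from dataset: {sorted(missing)[:5]}")
    n = ds.n_samples
    rows, ve, signs = {}, {}, {}
    for label in assignment.module_labels:
        feats = assignment.features_in(label)
        if not feats:
            raise ValueError(f"module {label} has no features")
        X = _standardize(ds.matrix[feats].to_numpy())
        U, S, _ = np.linalg.svd(X, full_matrices=False)
        e = U[:, 0] * np.sqrt(n - 1)
        sign = 1.0
        mean_profile = X.mean(axis=1)
        c = float(e @ (mean_profile - mean_profile.mean()))
        if c < 0:
            sign = -1.0
        e = e * sign
        rows[label] = e
        total = float((S**2).sum())
        ve[label] = float(S[0] ** 2 / total) if total > 0 else 0.0
        signs[label] = int(sign)
    eig = pd.DataFrame(rows, index=ds.sample_ids).T
    eig.index.name = "module_label"
    return EigengeneSet(
        eigengenes=eig,
        variance_explained=pd.Series(ve, name="variance_explained"),
        orientation_sign=pd.Series(signs, name="orientation_sign"),
    )


def merge_close_modules(
    ds: ExpressionDataset,
    assignment: ModuleAssignment,
    merge_cut_height: float = 0.25,
) -> tuple[ModuleAssignment, EigengeneSet]:
    """Merge modules whose eigengenes are highly correlated.

    Repeatedly finds the module pair with the smallest eigengene
    dissimilarity (1 - Pearson correlation); if it is strictly below
    ``merge_cut_height`` the pair is merged and all eigengenes are
    recomputed, until no pair is close enough. Recomputing every round
    keeps the outcome independent of merge order. ``merge_cut_height=0``
    therefore never merges.
    """
    if not 0.0 <= merge_cut_height <= 1.0:
        raise ValueError("merge_cut_height must be in [0, 1]")
    labels = assignment.labels.copy()
    while True:
        current = ModuleAssignment(labels=labels, dendrogram=assignment.dendrogram)
        eig = compute_eigengenes(ds, current)
        mods = eig.module_labels
        if len(mods) < 2 or merge_cut_height == 0.0:
            break
        corr = np.corrcoef(eig.eigengenes.to_numpy())
        d = 1.0 - corr
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(int(np.argmin(d)), d.shape)
        if d[i, j] >= merge_cut_height:
            break
        keep, absorb = sorted((mods[i], mods[j]))
        labels = labels.replace(absorb, keep)
        logger.info(
            "merging module %d into %d (eigengene dissimilarity %.3f)",
            absorb, keep, float(d[i, j]),
        )
    relabeled = _relabel_by_size(labels.to_numpy())
    final = ModuleAssignment(
        labels=pd.Series(relabeled, index=labels.index),
        dendrogram=assignment.dendrogram,
    )
    return final, compute_eigengenes(ds, final)
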