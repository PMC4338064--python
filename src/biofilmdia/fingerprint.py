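"""Community-fingerprint (T-RFLP / ARISA) analysis chain.

From per-sample fragment peak tables to: noise filtering (height > 50
fluorescence units, marker-specific size windows), T-Align-style fragment
binning at a 0.5 nt confidence interval, relative-abundance normalisation
with a <0.5% exclusion rule, square-root transform and Bray-Curtis
similarities (%), diversity indices (richness, Shannon H', Pielou J'), and
the PRIMER-style permutation statistics ANOSIM, SIMPER and SIMPROF with
group-average hierarchical clustering.  Relative abundance is peak-AREA
based; heights are carried for filtering only.

Community matrices are pandas DataFrames: rows = samples, columns = bin
consensus fragment sizes (strictly increasing floats); after
:func:`normalise` each row sums to 1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, ttest_ind

from .errors import DataError

HEIGHT_CUTOFF = 50.0            # fluorescence units; strictly-greater rule
ALIGN_TOLERANCE_NT = 0.5        # T-Align confidence interval
MIN_RELATIVE_ABUNDANCE = 0.005  # <0.5% of the profile is excluded
SIZE_WINDOWS = {"T-RF": (50.0, 500.0), "ARISA": (94.0, 827.0)}


@dataclass(frozen=True)
class FingerprintProfile:
    """One sample's fragment peaks: (size nt, height, area) plus marker type
    and valid size window."""

    sample_id: str
    peaks: pd.DataFrame            # columns: size_nt, height, area
    marker: str = "T-RF"
    size_window: tuple = None

    def __post_init__(self):
        df = pd.DataFrame(self.peaks, columns=["size_nt", "height", "area"])
        if ((df["height"] < 0).any() or (df["area"] < 0).any()):
            raise DataError("heights and areas must be non-negative")
        object.__setattr__(self, "peaks",
                           df.sort_values("size_nt").reset_index(drop=True))
        if self.size_window is None:
            if self.marker not in SIZE_WINDOWS:
                raise DataError(f"unknown marker {self.marker!r}; "
                                "supply size_window explicitly")
            object.__setattr__(self, "size_window", SIZE_WINDOWS[self.marker])


def filter_peaks(profile: FingerprintProfile,
                 height_cutoff: float = HEIGHT_CUTOFF) -> FingerprintProfile:
    """Noise filter: keep peaks with height strictly greater than the cutoff
    and size inside the marker's window (inclusive).  An empty result is
    allowed but flagged with a warning."""
    lo, hi = profile.size_window
    df = profile.peaks
    keep = (df["height"] > height_cutoff) & (df["size_nt"] >= lo) & (df["size_nt"] <= hi)
    out = df[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn(f"{profile.sample_id}: no peaks survive filtering")
    return replace(profile, peaks=out)


def _merge_within_sample(df: pd.DataFrame, tol: float) -> pd.DataFrame:
    """Merge a sample's peaks closer than ``tol`` nt (areas and heights
    summed, size = area-weighted mean), ascending-size order."""
    if df.empty:
        return df
    rows = []
    cur_sizes, cur_areas, cur_heights = [df.size_nt.iloc[0]], [df.area.iloc[0]], [df.height.iloc[0]]
    for _, r in df.iloc[1:].iterrows():
        ref = np.average(cur_sizes, weights=cur_areas) if sum(cur_areas) > 0 else np.mean(cur_sizes)
        if abs(r.size_nt - ref) < tol:
            cur_sizes.append(r.size_nt)
            cur_areas.append(r.area)
            cur_heights.append(r.height)
        else:
            rows.append((ref, sum(cur_heights), sum(cur_areas)))
            cur_sizes, cur_areas, cur_heights = [r.size_nt], [r.area], [r.height]
    ref = np.average(cur_sizes, weights=cur_areas) if sum(cur_areas) > 0 else np.mean(cur_sizes)
    rows.append((ref, sum(cur_heights), sum(cur_areas)))
    return pd.DataFrame(rows, columns=["size_nt", "height", "area"])


def align_fragments(profiles, tolerance: float = ALIGN_TOLERANCE_NT) -> pd.DataFrame:
    """T-Align-style two-pass binning into a samples x fragment-bins table of
    raw peak areas.

    Pass 1 merges peaks within each sample that are closer than the
    tolerance.  Pass 2 builds consensus bins over all samples' peaks in
    ascending size order: a peak joins an existing bin iff
    |size - bin consensus| < tolerance, where the consensus is the running
    mean of member sizes; otherwise it opens a new bin.  Deterministic.
    Aligning an already-binned dataset changes nothing (idempotence).
    """
    profiles = list(profiles)
    merged = {p.sample_id: _merge_within_sample(p.peaks, tolerance) for p in profiles}
    all_peaks = []
    for sid, df in merged.items():
        for _, r in df.iterrows():
            all_peaks.append((float(r.size_nt), sid, float(r.area)))
    all_peaks.sort(key=lambda t: t[0])

    bins: list[dict] = []   # {'sizes': [...], 'areas': {sample: area}}
    for size, sid, area in all_peaks:
        placed = False
        if bins:
            b = bins[-1]  # ascending order: only the latest bin can be close
            consensus = np.mean(b["sizes"])
            if abs(size - consensus) < tolerance:
                b["sizes"].append(size)
                b["areas"][sid] = b["areas"].get(sid, 0.0) + area
                placed = True
        if not placed:
            bins.append({"sizes": [size], "areas": {sid: area}})

    labels = [float(np.mean(b["sizes"])) for b in bins]
    table = pd.DataFrame(0.0, index=[p.sample_id for p in profiles], columns=labels)
    for lab, b in zip(labels, bins):
        for sid, area in b["areas"].items():
            table.loc[sid, lab] = area
    if len(table.columns) > 1 and not np.all(np.diff(table.columns) > 0):
        raise DataError("bin labels are not strictly increasing")
    return table


def normalise(matrix: pd.DataFrame,
              min_fraction: float = MIN_RELATIVE_ABUNDANCE,
              renormalise: bool = True) -> pd.DataFrame:
    """Within-sample relative abundance with the <0.5% exclusion rule.

    Entries contributing strictly less than ``min_fraction`` of their
    sample's total are zeroed (an entry at exactly 0.5% is retained); rows
    are then re-normalised to sum to 1 unless ``renormalise`` is False.
    """
    totals = matrix.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise DataError(f"empty sample(s): {bad}")
    rel = matrix.div(totals, axis=0)
    rel = rel.where(rel >= min_fraction, 0.0)
    if renormalise:
        totals2 = rel.sum(axis=1)
        if (totals2 <= 0).any():
            raise DataError("a sample lost all fragments to the abundance cutoff")
        rel = rel.div(totals2, axis=0)
    # drop bins that vanished everywhere
    return rel.loc[:, (rel > 0).any(axis=0)]


# ---------------------------------------------------------------------------
# similarity, diversity


def _sqrt_matrix(matrix: pd.DataFrame, transform: str) -> np.ndarray:
    x = matrix.to_numpy(dtype=float)
    if transform == "sqrt":
        return np.sqrt(x)
    if transform in (None, "none"):
        return x
    raise ValueError("transform must be 'sqrt' or 'none'")


def bray_curtis(matrix: pd.DataFrame, transform: str = "sqrt") -> pd.DataFrame:
    """Bray-Curtis similarity matrix in percent on (by default) square-root
    transformed abundances: 100 * (1 - sum|x-y| / sum(x+y)).  Symmetric with
    100 on the diagonal."""
    x = _sqrt_matrix(matrix, transform)
    d = squareform(pdist(x, metric="braycurtis"))
    sim = 100.0 * (1.0 - d)
    return pd.DataFrame(sim, index=matrix.index, columns=matrix.index)


def diversity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Richness S, Shannon H' (natural log) and Pielou J' = H'/ln S per
    sample; J' is NaN (flagged) when S = 1."""
    rel = matrix.div(matrix.sum(axis=1), axis=0)
    rows = []
    for sid, p in rel.iterrows():
        p = p[p > 0].to_numpy()
        s = int(p.size)
        if s == 0:
            raise DataError(f"sample {sid!r} has no fragments")
        h = float(-(p * np.log(p)).sum())
        j = h / np.log(s) if s > 1 else np.nan
        rows.append({"sample": sid, "richness": s, "shannon": h, "pielou": j})
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# ANOSIM


def _condensed_pairs(n: int):
    iu = np.triu_indices(n, k=1)
    return iu


def anosim(similarity: pd.DataFrame, labels, permutations=9999,
           seed: int | None = None) -> dict:
    """ANOSIM on a similarity (%) matrix: R and a permutation p-value.

    R = (mean between-group dissimilarity rank - mean within-group rank)
    divided by n(n-1)/4.  ``permutations`` may be an integer (random label
    permutations, seeded) or ``"exhaustive"`` to enumerate every distinct
    labelling; p is the fraction of permuted R >= observed (the observed
    labelling counts as one permutation in the random case).
    """
    labels = np.asarray(labels)
    sim = similarity.to_numpy(dtype=float)
    n = sim.shape[0]
    if labels.size != n:
        raise DataError("labels must match the similarity matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2 or counts.min() < 2:
        raise DataError("need >= 2 groups with >= 2 members each")
    i0, i1 = _condensed_pairs(n)
    dis = 100.0 - sim[i0, i1]
    ranks = rankdata(dis)
    denom = n * (n - 1) / 4.0

    def r_stat(lab):
        within = lab[i0] == lab[i1]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = r_stat(labels)
    if permutations == "exhaustive":
        perms = set(itertools.permutations(labels))
        count = sum(r_stat(np.asarray(p)) >= r_obs - 1e-12 for p in perms)
        p = count / len(perms)
        n_perm = len(perms)
    else:
        rng = np.random.default_rng(seed)
        count = 1  # observed labelling
        for _ in range(int(permutations)):
            count += r_stat(rng.permutation(labels)) >= r_obs - 1e-12
        p = count / (int(permutations) + 1)
        n_perm = int(permutations)
    return {"R": float(r_obs), "p": float(p), "permutations": n_perm}


# ---------------------------------------------------------------------------
# SIMPER


def simper(matrix: pd.DataFrame, labels, transform: str = "sqrt") -> dict:
    """Decompose the average between-group Bray-Curtis dissimilarity (%)
    into per-bin contributions; contributions sum to the overall average
    dissimilarity.  Also reports each group's average within-group
    similarity (the 'similarity between replicates').
    """
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if uniq.size != 2:
        raise DataError("SIMPER compares exactly two groups")
    x = _sqrt_matrix(matrix, transform)
    ga = x[labels == uniq[0]]
    gb = x[labels == uniq[1]]

    contrib = np.zeros(x.shape[1])
    n_pairs = 0
    for xa in ga:
        for xb in gb:
            denom = (xa + xb).sum()
            if denom == 0:
                continue
            contrib += 100.0 * np.abs(xa - xb) / denom
            n_pairs += 1
    contrib /= max(n_pairs, 1)
    table = pd.DataFrame({"contribution_pct": contrib}, index=matrix.columns)
    table["contribution_rel"] = (table["contribution_pct"] / table["contribution_pct"].sum()
                                 if table["contribution_pct"].sum() > 0 else 0.0)
    table = table.sort_values("contribution_pct", ascending=False)

    within = {}
    for g in uniq:
        gx = x[labels == g]
        if gx.shape[0] < 2:
            raise DataError(f"group {g!r} needs >= 2 members for within-group similarity")
        d = pdist(gx, metric="braycurtis")
        within[g] = float(100.0 * (1.0 - d.mean()))
    return {"contributions": table,
            "average_dissimilarity": float(contrib.sum()),
            "within_group_similarity": within}


# ---------------------------------------------------------------------------
# SIMPROF + clustering


def _bc_profile_batch(x: np.ndarray) -> np.ndarray:
    """Sorted Bray-Curtis similarity (%) profiles for a batch of datasets.

    x: (B, n, k) already-transformed abundances; returns (B, n(n-1)/2)
    row-sorted similarity profiles."""
    b, n, _ = x.shape
    i0, i1 = _condensed_pairs(n)
    num = np.abs(x[:, i0, :] - x[:, i1, :]).sum(axis=2)
    den = (x[:, i0, :] + x[:, i1, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / den, 0.0)
    return np.sort(100.0 * (1.0 - d), axis=1)


def simprof_test(matrix: pd.DataFrame, n_perm: int = 20000,
                 seed: int | None = None, transform: str = "sqrt") -> dict:
    """Similarity-profile permutation test for multivariate structure.

    The pi statistic is the summed absolute departure of the observed ordered
    similarity profile from the mean profile of datasets built by permuting
    each fragment bin's values independently across samples.  Half the
    permutations build the expected profile, half the null distribution of
    pi; p = (1 + #null >= observed) / (1 + n_null).
    """
    x = _sqrt_matrix(matrix, transform)
    n, k = x.shape
    if n < 3:
        raise DataError("SIMPROF needs >= 3 samples")
    rng = np.random.default_rng(seed)
    obs = _bc_profile_batch(x[None])[0]
    b1 = max(n_perm // 2, 1)
    b2 = max(n_perm - b1, 1)

    def permuted(batch):
        idx = np.argsort(rng.random((batch, n, k)), axis=1)
        return np.take_along_axis(np.broadcast_to(x, (batch, n, k)), idx, axis=1)

    mean_profile = _bc_profile_batch(permuted(b1)).mean(axis=0)
    pi_obs = float(np.abs(obs - mean_profile).sum())
    null_pi = np.abs(_bc_profile_batch(permuted(b2)) - mean_profile).sum(axis=1)
    p = float((1 + np.count_nonzero(null_pi >= pi_obs - 1e-12)) / (1 + b2))
    return {"pi": pi_obs, "p": p, "n_perm": b1 + b2}


@dataclass
class SimprofNode:
    """One internal dendrogram node with its SIMPROF verdict."""

    samples: list
    height: float
    pi: float | None
    p: float | None
    significant: bool


@dataclass
class SimprofClustering:
    linkage: np.ndarray
    sample_ids: list
    nodes: list = field(default_factory=list)
    newick: str = ""


def simprof_cluster(matrix: pd.DataFrame, n_perm: int = 20000,
                    alpha: float = 0.05, seed: int | None = None,
                    transform: str = "sqrt") -> SimprofClustering:
    """Group-average hierarchical clustering on Bray-Curtis dissimilarity
    with top-down SIMPROF assessment.

    Starting at the root, each node with >= 3 samples is tested; if the test
    rejects (real structure) its children are examined in turn, otherwise
    the whole subtree is flagged homogeneous (the dendrogram's 'red lines').
    """
    if matrix.shape[0] < 3:
        raise DataError("clustering needs >= 3 samples")
    x = _sqrt_matrix(matrix, transform)
    d = pdist(x, metric="braycurtis")
    link = hierarchy.linkage(d, method="average")
    tree = hierarchy.to_tree(link)
    ids = list(matrix.index)
    rng = np.random.default_rng(seed)
    result = SimprofClustering(linkage=link, sample_ids=ids)

    def visit(node, test: bool):
        if node.is_leaf():
            return
        leaves = node.pre_order(lambda lf: lf.id)
        verdict = SimprofNode(samples=[ids[i] for i in leaves],
                              height=float(node.dist), pi=None, p=None,
                              significant=False)
        if test and len(leaves) >= 3:
            sub = matrix.iloc[sorted(leaves)]
            res = simprof_test(sub, n_perm=n_perm,
                               seed=int(rng.integers(2**31)), transform=transform)
            verdict.pi, verdict.p = res["pi"], res["p"]
            verdict.significant = res["p"] < alpha
        result.nodes.append(verdict)
        visit(node.left, test=verdict.significant)
        visit(node.right, test=verdict.significant)

    visit(tree, test=True)
    result.newick = _to_newick(tree, ids,
                               {tuple(sorted(nd.samples)): nd for nd in result.nodes})
    return result


def _to_newick(node, ids, verdicts) -> str:
    """Newick with SIMPROF verdicts as node comments."""

    def tag_of(n):
        key = tuple(sorted(ids[i] for i in n.pre_order(lambda lf: lf.id)))
        v = verdicts.get(key)
        if v is None:
            return ""
        return f"[&simprof={'significant' if v.significant else 'homogeneous'}]"

    def fmt(n, parent_dist):
        length = max(parent_dist - n.dist, 0.0)
        if n.is_leaf():
            return f"{ids[n.id]}:{parent_dist:.6g}"
        return f"({fmt(n.left, n.dist)},{fmt(n.right, n.dist)}){tag_of(n)}:{length:.6g}"

    return (f"({fmt(node.left, node.dist)},{fmt(node.right, node.dist)})"
            f"{tag_of(node)};")


# ---------------------------------------------------------------------------
# index comparison (Welch t-tests)


def compare_indices(indices: pd.DataFrame, labels) -> pd.DataFrame:
    """Welch two-sample t-test per diversity index (unequal variances,
    fractional Welch-Satterthwaite df), reporting t, df and p."""
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if uniq.size != 2:
        raise DataError("index comparison expects exactly two groups")
    rows = []
    for col in indices.columns:
        a = indices[col].to_numpy(dtype=float)[labels == uniq[0]]
        b = indices[col].to_numpy(dtype=float)[labels == uniq[1]]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            raise DataError(f"{col}: each group needs >= 2 observations")
        res = ttest_ind(a, b, equal_var=False)
        rows.append({"index": col, "t": float(res.statistic),
                     "df": float(res.df), "p": float(res.pvalue)})
    return pd.DataFrame(rows).set_index("index")


# ---------------------------------------------------------------------------
# Local Southern fragment sizing (optional op)


def _reciprocal_fit(migrations, sizes):
    """Exact 3-point fit of L = c/(m - m0) + L0."""
    m1, m2, m3 = migrations
    l1, l2, l3 = sizes
    a = l1 - l2
    b = l2 - l3
    denom = a * (m3 - m2) - b * (m2 - m1)
    if denom == 0:
        raise DataError("degenerate size-standard triplet")
    m0 = (a * (m3 - m2) * m1 - b * (m2 - m1) * m3) / denom
    c = a / (1.0 / (m1 - m0) - 1.0 / (m2 - m0))
    l0 = l1 - c / (m1 - m0)
    return c, m0, l0


def size_fragments_local_southern(query_migrations, standards) -> np.ndarray:
    """Local Southern sizing against internal standards.

    ``standards``: sequence of (migration, known size nt) in ascending
    migration order.  Each query is sized by fitting the reciprocal mobility
    model to the two overlapping triplets of flanking standards and averaging
    the two fitted sizes; a query outside the bracketed range raises.
    """
    std = sorted((float(m), float(s)) for m, s in standards)
    if len(std) < 4:
        raise DataError("need >= 4 size-standard points")
    migs = np.array([m for m, _ in std])
    sizes = np.array([s for _, s in std])
    out = []
    for q in np.atleast_1d(np.asarray(query_migrations, dtype=float)):
        # q lies in the interval (migs[i-1], migs[i]]; the two overlapping
        # flanking triplets are (i-2, i-1, i) and (i-1, i, i+1)
        i = int(np.searchsorted(migs, q))
        t1 = (i - 2, i - 1, i)
        t2 = (i - 1, i, i + 1)
        if t1[0] < 0 or t2[2] >= len(std):
            raise DataError(f"query {q} not bracketed by >= 4 standards")
        vals = []
        for t in (t1, t2):
            c, m0, l0 = _reciprocal_fit(migs[list(t)], sizes[list(t)])
            vals.append(c / (q - m0) + l0)
        out.append(float(np.mean(vals)))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# peak-table I/O


def read_peak_table(path, marker: str = "T-RF") -> list:
    """Read a delimited peak table (columns: sample_id, size_nt, height,
    area) into per-sample profiles."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_id", "size_nt", "height", "area"}
    if not required.issubset(df.columns):
        raise DataError(f"peak table must have columns {sorted(required)}")
    return [FingerprintProfile(sample_id=str(sid),
                               peaks=g[["size_nt", "height", "area"]],
                               marker=marker)
            for sid, g in df.groupby("sample_id", sort=True)]


def write_peak_table(profiles, path) -> None:
    frames = []
    for p in profiles:
        df = p.peaks.copy()
        df.insert(0, "sample_id", p.sample_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
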