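"""TSS cluster calling from per-base 5'-end counts.

The procedure has four steps:

1. *Cluster areas*: maximal-scoring-segment clustering of pooled 5'-end
   counts (the paraclu recursion).  Each segment is optimal for a density
   interval [d_min, d_max); areas are kept if d_max/d_min >= min_stability,
   total count >= min_count and span <= max_length, and nested areas are
   collapsed to the outermost passing one, so areas are disjoint per strand.
2. *Subpeaks*: local-maxima decomposition within each area; internal
   boundaries at the midpoint between adjacent summits.
3. *Filters*: internal-priming artifacts are removed by their low (<15%)
   count-weighted fraction of reads carrying a non-genomic 5' G
   (mitochondrial clusters, which are uncapped, are instead kept only when
   they overlap an annotated start); minor isoforms at <= 10% of the gene's
   most abundant isoform in every analysis are removed.
4. *Final boundaries*: surviving summits are mapped back onto their parent
   areas and boundaries re-drawn at midpoints, so the surviving clusters
   partition each parent area.

Coordinates are 0-based half-open; the 5' end of a minus-strand cluster is
its highest genomic coordinate and all tie-breaks are transcript-oriented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hp5kit.io import Annotation, Transcript

__all__ = [
    "ClusterArea",
    "TssCluster",
    "pool_tracks",
    "paraclu_segments",
    "call_cluster_areas",
    "decompose_subpeaks",
    "filter_artifact_clusters",
    "filter_minor_isoforms",
    "finalize_boundaries",
    "assign_clusters_to_genes",
    "assign_representative_transcript",
    "isoform_sequence",
    "cluster_tss",
]

MITO_CHROMS = frozenset({"chrM", "MT", "chrMT", "M"})


@dataclass
class ClusterArea:
    chrom: str
    strand: str
    start: int  # 0-based half-open, first site base
    end: int  # one past last site base
    total: float
    min_density: float
    max_density: float

    @property
    def stability(self) -> float:
        if self.min_density <= 0:
            return float("inf")
        return self.max_density / self.min_density


@dataclass
class TssCluster:
    cluster_id: str
    chrom: str
    strand: str
    start: int
    end: int
    summit: int
    counts: np.ndarray  # per-base counts over [start, end)
    g_fraction: float | None = None  # count-weighted mean over the cluster
    area_index: int = -1
    gene_id: str | None = None
    transcript_id: str | None = None
    cds_start: int | None = None  # nt offset of AUG in the isoform sequence
    cds_end: int | None = None  # nt offset one past the stop codon
    cds_flagged: bool = False  # CDS undefined / redefinition failed
    mitochondrial: bool = False
    sequence: str | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


# ---------------------------------------------------------------------------
# Step 1: maximal-scoring-segment cluster areas
# ---------------------------------------------------------------------------

def pool_tracks(tracks) -> pd.DataFrame:
    """Sum per-base counts over samples; g_fraction pooled count-weighted."""
    frames = list(tracks.values()) if isinstance(tracks, dict) else list(tracks)
    df = pd.concat(frames, ignore_index=True)
    df = df.assign(weighted=df["count"] * df["g_fraction"])
    out = df.groupby(["chrom", "pos", "strand"], as_index=False).agg(
        count=("count", "sum"), weighted=("weighted", "sum")
    )
    out["g_fraction"] = out["weighted"] / out["count"]
    return out.drop(columns="weighted").sort_values(
        ["chrom", "pos", "strand"], kind="mergesort", ignore_index=True
    )


def paraclu_segments(
    positions: np.ndarray, counts: np.ndarray
) -> list[tuple[int, int, float, float]]:
    """All density-maximal segments of a sorted 1-D site list.

    A segment of sites is scored ``total - d * span`` (span in bases,
    including internal gaps); as the density penalty d decreases, optimal
    segments merge, giving a laminar hierarchy.  Returns site-index
    segments ``(i, j, d_min, d_max)``: sites[i:j] is optimal for densities
    in [d_min, d_max).  This is the recursion of the paraclu peak caller:
    a segment breaks at the density at which its weakest prefix or suffix
    (including the adjoining gap) stops paying for itself.
    """
    positions = np.asarray(positions, dtype=np.int64)
    counts = np.asarray(counts, dtype=float)
    n = len(positions)
    if n == 0:
        return []
    segs: list[tuple[int, int, float, float]] = []
    stack: list[tuple[int, int, float]] = [(0, n, 0.0)]
    while stack:
        b, e, min_d = stack.pop()
        if e - b <= 0:
            continue
        if e - b == 1:
            segs.append((b, e, min_d, float("inf")))
            continue
        pos = positions[b:e]
        val = counts[b:e]
        # prefix [b, b+k) has density sum(val[:k]) / (pos[k] - pos[0]):
        # cutting it also discards the gap up to the next remaining site
        csum = np.cumsum(val)
        pref_dens = csum[:-1] / (pos[1:] - pos[0])
        k_pref = int(np.argmin(pref_dens))
        pref_min = float(pref_dens[k_pref])
        # suffix [b+k, e) has density sum(val[k:]) / (pos[-1] - pos[k-1])
        suf_dens = (csum[-1] - csum[:-1]) / (pos[-1] - pos[:-1])
        k_suf = int(np.argmin(suf_dens))
        suf_min = float(suf_dens[k_suf])
        break_d = min(pref_min, suf_min)
        if break_d > min_d:
            segs.append((b, e, min_d, break_d))
        new_min = max(min_d, break_d)
        if pref_min <= suf_min:
            split = b + k_pref + 1
        else:
            split = b + k_suf + 1
        stack.append((b, split, new_min))
        stack.append((split, e, new_min))
    return segs


def call_cluster_areas(
    tracks,
    min_stability: float = 2.0,
    min_count: float = 30.0,
    max_length: int = 200,
) -> list[ClusterArea]:
    """Disjoint cluster areas per strand from pooled 5'-end tracks.

    Segments passing the stability/count/length cutoffs are reduced to the
    outermost passing segment of each nested family (the standard workflow
    of the paraclu tool).
    """
    pooled = tracks if isinstance(tracks, pd.DataFrame) else pool_tracks(tracks)
    areas: list[ClusterArea] = []
    for (chrom, strand), sub in pooled.groupby(["chrom", "strand"], sort=True):
        sub = sub.sort_values("pos", kind="mergesort")
        pos = sub["pos"].to_numpy()
        cnt = sub["count"].to_numpy(dtype=float)
        keep = []
        for i, j, dmin, dmax in paraclu_segments(pos, cnt):
            span = int(pos[j - 1] - pos[i] + 1)
            total = float(cnt[i:j].sum())
            stability = float("inf") if dmin <= 0 else dmax / dmin
            if stability >= min_stability and total >= min_count and span <= max_length:
                keep.append((int(pos[i]), int(pos[j - 1]) + 1, total, dmin, dmax))
        keep.sort(key=lambda t: (t[0], -(t[1] - t[0])))
        last_end = -1
        for start, end, total, dmin, dmax in keep:
            if start < last_end:  # nested or overlapping an outer kept area
                continue
            areas.append(ClusterArea(chrom, strand, start, end, total, dmin, dmax))
            last_end = end
    return areas


# ---------------------------------------------------------------------------
# Step 2: subpeak decomposition
# ---------------------------------------------------------------------------

def decompose_subpeaks(
    counts: np.ndarray,
    strand: str = "+",
    min_separation: int = 5,
    min_rel_height: float = 0.10,
) -> tuple[list[int], list[int]]:
    """Summits and internal boundaries within one cluster area.

    ``counts`` is the per-base profile over the area (offset coordinates).
    Summits are local maxima >= min_rel_height * max, at least
    ``min_separation`` bases apart (greedy by height; ties resolved toward
    the 5' end, which on the minus strand is the higher offset).  Internal
    boundaries fall at the midpoint between adjacent summits (left-closed).
    """
    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    if n == 0 or counts.max() <= 0:
        return [], []
    # plateau-aware local maxima; candidate = 5'-most base of the plateau
    cands = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and counts[j + 1] == counts[i]:
            j += 1
        left = counts[i - 1] if i > 0 else -np.inf
        right = counts[j + 1] if j + 1 < n else -np.inf
        if counts[i] > 0 and counts[i] >= left and counts[i] >= right:
            cands.append(i if strand == "+" else j)
        i = j + 1
    thresh = min_rel_height * counts.max()
    cands = [c for c in cands if counts[c] >= thresh]
    # greedy by height, ties toward the 5' end
    order = sorted(cands, key=lambda c: (-counts[c], c if strand == "+" else -c))
    summits: list[int] = []
    for c in order:
        if all(abs(c - s) >= min_separation for s in summits):
            summits.append(c)
    summits.sort()
    boundaries = [(summits[k] + summits[k + 1] + 1) // 2 for k in range(len(summits) - 1)]
    return summits, boundaries


def _area_profile(area: ClusterArea, pooled: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    sub = pooled[
        (pooled["chrom"] == area.chrom)
        & (pooled["strand"] == area.strand)
        & (pooled["pos"] >= area.start)
        & (pooled["pos"] < area.end)
    ]
    counts = np.zeros(area.end - area.start)
    gfrac = np.full(area.end - area.start, np.nan)
    idx = sub["pos"].to_numpy() - area.start
    counts[idx] = sub["count"].to_numpy(dtype=float)
    if "g_fraction" in sub.columns:
        gfrac[idx] = sub["g_fraction"].to_numpy(dtype=float)
    return counts, gfrac


def _make_cluster(area_index, area, profile, gfrac, start_off, end_off, summit_off):
    counts = profile[start_off:end_off]
    g = gfrac[start_off:end_off]
    w = counts[~np.isnan(g)]
    gmean = float((w * g[~np.isnan(g)]).sum() / w.sum()) if w.sum() > 0 else None
    return TssCluster(
        cluster_id=f"{area.chrom}:{area.start + summit_off}:{area.strand}",
        chrom=area.chrom,
        strand=area.strand,
        start=area.start + start_off,
        end=area.start + end_off,
        summit=area.start + summit_off,
        counts=counts.copy(),
        g_fraction=gmean,
        area_index=area_index,
        mitochondrial=area.chrom in MITO_CHROMS,
    )


def clusters_from_areas(
    areas: list[ClusterArea],
    pooled: pd.DataFrame,
    min_separation: int = 5,
    min_rel_height: float = 0.10,
) -> list[TssCluster]:
    """Steps 1+2 combined: subclusters bounded at midpoints between summits."""
    clusters: list[TssCluster] = []
    for ai, area in enumerate(areas):
        profile, gfrac = _area_profile(area, pooled)
        summits, bounds = decompose_subpeaks(
            profile, area.strand, min_separation, min_rel_height
        )
        edges = [0] + bounds + [len(profile)]
        for k, s in enumerate(summits):
            clusters.append(
                _make_cluster(ai, area, profile, gfrac, edges[k], edges[k + 1], s)
            )
    return clusters


# ---------------------------------------------------------------------------
# Step 3: filters
# ---------------------------------------------------------------------------

def filter_artifact_clusters(
    clusters: list[TssCluster],
    annotation: Annotation | None = None,
    g_threshold: float = 0.15,
) -> list[TssCluster]:
    """Drop putative internal-priming clusters.

    Non-mitochondrial clusters whose count-weighted non-genomic-G fraction
    is below ``g_threshold`` are removed.  Mitochondrial mRNAs are not
    capped, so mitochondrial clusters are exempt from the G rule but kept
    only if they overlap an annotated transcript start.
    """
    out = []
    for c in clusters:
        if c.mitochondrial:
            if annotation is None:
                raise ValueError(
                    "mitochondrial clusters require an annotation to check "
                    "overlap with annotated starts"
                )
            tss = annotation.annotated_tss_positions(c.chrom, c.strand)
            if ((tss >= c.start) & (tss < c.end)).any():
                out.append(c)
            continue
        if c.g_fraction is None:
            raise ValueError(
                f"cluster {c.cluster_id} lacks g_fraction; the artifact "
                "filter cannot run without non-genomic-G information"
            )
        if c.g_fraction >= g_threshold:
            out.append(c)
    return out


def filter_minor_isoforms(
    clusters: list[TssCluster],
    abundances: pd.DataFrame,
    max_relative: float = 0.10,
) -> list[TssCluster]:
    """Drop clusters at <= ``max_relative`` of the gene's top cluster.

    ``abundances``: rows indexed by cluster_id, one column per analysis
    (reads starting within the cluster in that analysis).  A cluster is
    kept if it exceeds the threshold in *any* analysis; clusters without a
    gene assignment are left untouched.
    """
    by_gene: dict[str, list[TssCluster]] = {}
    for c in clusters:
        if c.gene_id is not None:
            by_gene.setdefault(c.gene_id, []).append(c)
    drop: set[str] = set()
    for gid, group in by_gene.items():
        ab = abundances.loc[[c.cluster_id for c in group]]
        top = ab.max(axis=0)
        if (top <= 0).all():
            warnings.warn(f"gene {gid}: zero total abundance; all clusters dropped")
            drop.update(c.cluster_id for c in group)
            continue
        rel = ab.div(top.where(top > 0, np.nan), axis=1)
        minor = (rel <= max_relative) | rel.isna()
        drop.update(rel.index[minor.all(axis=1)])
    return [c for c in clusters if c.cluster_id not in drop]


def cluster_abundances(
    clusters: list[TssCluster], analyses: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Reads starting within each cluster, per analysis track."""
    cols = {}
    for name, track in analyses.items():
        vals = []
        for c in clusters:
            sub = track[
                (track["chrom"] == c.chrom)
                & (track["strand"] == c.strand)
                & (track["pos"] >= c.start)
                & (track["pos"] < c.end)
            ]
            vals.append(float(sub["count"].sum()))
        cols[name] = vals
    return pd.DataFrame(cols, index=[c.cluster_id for c in clusters])


# ---------------------------------------------------------------------------
# Step 4: final boundaries
# ---------------------------------------------------------------------------

def finalize_boundaries(
    clusters: list[TssCluster], areas: list[ClusterArea], pooled: pd.DataFrame
) -> list[TssCluster]:
    """Re-draw boundaries so surviving clusters partition their parent area.

    Outer boundaries come from the parent area; internal boundaries are the
    midpoints between surviving summits.  Areas whose summits were all
    filtered are dropped.
    """
    by_area: dict[int, list[TssCluster]] = {}
    for c in clusters:
        by_area.setdefault(c.area_index, []).append(c)
    out: list[TssCluster] = []
    for ai in sorted(by_area):
        group = sorted(by_area[ai], key=lambda c: c.summit)
        area = areas[ai]
        profile, gfrac = _area_profile(area, pooled)
        summits = [c.summit - area.start for c in group]
        bounds = [(summits[k] + summits[k + 1] + 1) // 2 for k in range(len(summits) - 1)]
        edges = [0] + bounds + [len(profile)]
        for k, old in enumerate(group):
            nc = _make_cluster(ai, area, profile, gfrac, edges[k], edges[k + 1], summits[k])
            nc.gene_id = old.gene_id
            nc.cluster_id = old.cluster_id
            nc.notes = list(old.notes)
            out.append(nc)
    return out


# ---------------------------------------------------------------------------
# Gene and transcript assignment
# ---------------------------------------------------------------------------

def assign_clusters_to_genes(
    clusters: list[TssCluster], annotation: Annotation, margin: int = 50
) -> list[TssCluster]:
    """Assign each cluster to the gene whose +/-50 bp-extended locus covers
    its summit on the matching strand.

    Overlapping-gene ties go to the gene with the nearest annotated TSS,
    then to the 5'-most gene (transcript orientation).
    """
    for c in clusters:
        hits = []
        for g in annotation.genes_on(c.chrom):
            if g.strand != c.strand:
                continue
            if g.start - margin <= c.summit < g.end + margin:
                dist = min(abs(t.tss - c.summit) for t in g.transcripts)
                five_prime = g.start if c.strand == "+" else -g.end
                hits.append((dist, five_prime, g.gene_id))
        c.gene_id = min(hits)[2] if hits else None
    return clusters


def isoform_sequence(
    summit: int, transcript: Transcript, genome
) -> tuple[str, int]:
    """mRNA sequence of the isoform starting at ``summit``.

    Returns ``(sequence, shift)`` where ``shift`` is the offset of the new
    5' end relative to the transcript's annotated 5' end (negative when the
    summit lies upstream; that extension is genomic/unspliced).  A summit in
    an intron starts the isoform at the next exonic base.
    """
    chrom_seq = genome[transcript.chrom]
    spliced = transcript.spliced_sequence(genome)
    pos = transcript.exonic_positions()
    if transcript.strand == "+":
        if summit < pos[0]:
            gap = str(chrom_seq[summit : pos[0]])
            return gap + spliced, -(pos[0] - summit)
        idx = int(np.searchsorted(pos, summit))
    else:
        if summit > pos[0]:
            gap = _revcomp(str(chrom_seq[pos[0] + 1 : summit + 1]))
            return gap + spliced, -(summit - pos[0])
        idx = int(np.searchsorted(-pos, -summit))
    idx = min(idx, len(pos) - 1)
    return spliced[idx:], idx


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def assign_representative_transcript(
    cluster: TssCluster, annotation: Annotation, genome
) -> TssCluster:
    """Pick the gene transcript with the annotated TSS nearest the summit
    (tie -> longer CDS) and derive the isoform sequence and CDS.

    If the summit lies downstream of the annotated start codon, the CDS
    start moves to the most upstream in-frame AUG downstream of the summit;
    if none precedes the stop codon (or the gene has no CDS), the CDS is
    undefined and the cluster flagged.
    """
    if cluster.gene_id is None:
        raise ValueError(f"cluster {cluster.cluster_id} has no gene assignment")
    gene = annotation.genes[cluster.gene_id]
    best = min(
        gene.transcripts,
        key=lambda t: (abs(t.tss - cluster.summit), -(t.cds_length() or 0), t.transcript_id),
    )
    cluster.transcript_id = best.transcript_id
    seq, shift = isoform_sequence(cluster.summit, best, genome)
    cluster.sequence = seq
    cds_off = best.cds_offset()
    if cds_off is None or best.cds_length() is None:
        cluster.cds_start = cluster.cds_end = None
        cluster.cds_flagged = True
        cluster.notes.append("no annotated CDS")
        return cluster
    cds_len = best.cds_length()
    new_start = cds_off - shift
    stop_off = new_start + cds_len  # one past the stop codon in new coords
    if new_start >= 0:
        cluster.cds_start, cluster.cds_end = new_start, stop_off
        cluster.cds_flagged = False
        return cluster
    # summit downstream of the annotated AUG: scan in-frame AUGs
    q = new_start % 3
    found = None
    while q + 3 <= stop_off - 3:
        if seq[q : q + 3] == "ATG":
            found = q
            break
        q += 3
    if found is None:
        cluster.cds_start = cluster.cds_end = None
        cluster.cds_flagged = True
        cluster.notes.append("no in-frame AUG downstream of summit")
    else:
        cluster.cds_start, cluster.cds_end = found, stop_off
        cluster.cds_flagged = False
        cluster.notes.append("CDS redefined to downstream in-frame AUG")
    return cluster


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def cluster_tss(
    tracks,
    annotation: Annotation,
    genome,
    analyses: dict[str, pd.DataFrame] | None = None,
    min_stability: float = 2.0,
    min_count: float = 30.0,
    max_length: int = 200,
    min_separation: int = 5,
    min_rel_height: float = 0.10,
    g_threshold: float = 0.15,
    minor_max_relative: float = 0.10,
    assign_transcripts: bool = True,
) -> list[TssCluster]:
    """Full pipeline: areas -> subpeaks -> filters -> final boundaries.

    ``tracks`` are pooled for cluster definition; ``analyses`` (name ->
    track) define the abundance sets for the minor-isoform rule and default
    to the pooled track as a single analysis.
    """
    pooled = tracks if isinstance(tracks, pd.DataFrame) else pool_tracks(tracks)
    areas = call_cluster_areas(pooled, min_stability, min_count, max_length)
    clusters = clusters_from_areas(areas, pooled, min_separation, min_rel_height)
    clusters = filter_artifact_clusters(clusters, annotation, g_threshold)
    clusters = assign_clusters_to_genes(clusters, annotation)
    if analyses is None:
        analyses = {"pooled": pooled}
    ab = cluster_abundances(clusters, analyses)
    clusters = filter_minor_isoforms(clusters, ab, minor_max_relative)
    clusters = finalize_boundaries(clusters, areas, pooled)
    if assign_transcripts:
        for c in clusters:
            if c.gene_id is not None:
                assign_representative_transcript(c, annotation, genome)
    return clusters


def clusters_to_frame(clusters: list[TssCluster]) -> pd.DataFrame:
    """Flat table view (one row per cluster) for writing to disk."""
    return pd.DataFrame(
        [
            dict(
                cluster_id=c.cluster_id, chrom=c.chrom, strand=c.strand,
                start=c.start, end=c.end, summit=c.summit, total=c.total,
                g_fraction=c.g_fraction, gene_id=c.gene_id,
                transcript_id=c.transcript_id, cds_start=c.cds_start,
                cds_end=c.cds_end, cds_flagged=c.cds_flagged,
                mitochondrial=c.mitochondrial,
            )
            for c in clusters
        ]
    )
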