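import numpy as np
import pandas as pd
import pytest

from conftest import make_track
from hp5kit import io
from hp5kit.tss_clustering import (
    TssCluster,
    assign_clusters_to_genes,
    assign_representative_transcript,
    call_cluster_areas,
    cluster_abundances,
    clusters_from_areas,
    decompose_subpeaks,
    filter_artifact_clusters,
    filter_minor_isoforms,
    finalize_boundaries,
    isoform_sequence,
    paraclu_segments,
    pool_tracks,
)

# ---------------------------------------------------------------------------
# Brute-force oracle for the maximal-scoring-segment recursion
# ---------------------------------------------------------------------------


def _best_segmentation(pos, cnt, d, lo, hi):
    """Disjoint best-scoring segments at density penalty d, by exhaustive
    search: pick the argmax segment (score = total - d * base span), then
    recurse left and right of it."""
    if lo > hi:
        return []
    best, best_sc = None, -np.inf
    for i in range(lo, hi + 1):
        tot = 0.0
        for j in range(i, hi + 1):
            tot += cnt[j]
            sc = tot - d * (pos[j] - pos[i] + 1)
            if sc > best_sc + 1e-9:
                best, best_sc = (i, j), sc
    i, j = best
    return (_best_segmentation(pos, cnt, d, lo, i - 1)
            + [(i, j)]
            + _best_segmentation(pos, cnt, d, j + 1, hi))


def oracle_segments(pos, cnt):
    """All segments optimal for some density, with their density interval,
    found by sweeping every critical density."""
    n = len(pos)
    crit = set()
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(i, j):
                wp = sum(cnt[i : k + 1])
                ws = sum(cnt[k + 1 : j + 1])
                crit.add(wp / (pos[k + 1] - pos[i]))
                crit.add(ws / (pos[j] - pos[k]))
    crit = sorted(crit)
    if not crit:
        return {(0, 0): (0.0, np.inf)}
    points = ([crit[0] * 0.5]
              + [(a + b) / 2 for a, b in zip(crit, crit[1:])]
              + [crit[-1] * 2])
    bounds = [0.0] + crit + [np.inf]
    found: dict[tuple, list[int]] = {}
    for idx, d in enumerate(points):
        for seg in _best_segmentation(pos, cnt, d, 0, n - 1):
            found.setdefault(seg, []).append(idx)
    out = {}
    for seg, idxs in found.items():
        out[seg] = (bounds[min(idxs)], bounds[max(idxs) + 1])
    return out


class TestParaclu:
    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("n", [2, 5, 10, 20])
    def test_matches_brute_force_on_small_inputs(self, seed, n):
        rng = np.random.default_rng(1000 * n + seed)
        pos = np.sort(rng.choice(np.arange(500), size=n, replace=False))
        cnt = rng.integers(1, 80, size=n).astype(float)
        got = {
            (pos[i], pos[j - 1]): (dmin, dmax)
            for i, j, dmin, dmax in paraclu_segments(pos, cnt)
        }
        expected = {
            (pos[i], pos[j]): iv for (i, j), iv in oracle_segments(pos, cnt).items()
        }
        assert set(got) == set(expected)
        for seg in got:
            g, e = got[seg], expected[seg]
            assert np.isclose(g[0], e[0], rtol=1e-9, atol=1e-12)
            assert (np.isinf(g[1]) and np.isinf(e[1])) or np.isclose(g[1], e[1], rtol=1e-9)

    def test_single_spike_gives_one_area(self):
        track = make_track([100], [100])
        areas = call_cluster_areas(track, min_count=30)
        assert len(areas) == 1
        assert (areas[0].start, areas[0].end) == (100, 101)

    def test_two_distant_spikes_give_two_areas(self):
        track = make_track([100, 10_100], [100, 100])
        areas = call_cluster_areas(track, min_count=30)
        assert [(a.start, a.end) for a in areas] == [(100, 101), (10_100, 10_101)]

    def test_all_below_min_count_empty(self):
        track = make_track([100, 200], [10, 10])
        assert call_cluster_areas(track, min_count=30) == []

    def test_empty_track_empty_result(self):
        track = make_track([], [])
        assert call_cluster_areas(track) == []

    def test_areas_disjoint_per_strand(self, small_tracks):
        pooled = pool_tracks(small_tracks)
        areas = call_cluster_areas(pooled)
        by_key = {}
        for a in areas:
            by_key.setdefault((a.chrom, a.strand), []).append((a.start, a.end))
        for ivs in by_key.values():
            ivs.sort()
            assert all(b1 <= a2 for (_, b1), (a2, _) in zip(ivs, ivs[1:]))
        assert all(a.stability >= 2 and a.total >= 30
                   and a.end - a.start <= 200 for a in areas)


class TestSubpeaks:
    def test_unimodal_profile_single_summit(self):
        summits, bounds = decompose_subpeaks(np.array([1, 5, 20, 5, 1.0]))
        assert summits == [2] and bounds == []

    def test_two_equal_peaks_boundary_at_midpoint(self):
        counts = np.zeros(50)
        counts[10] = counts[30] = 100
        summits, bounds = decompose_subpeaks(counts)
        assert summits == [10, 30]
        assert bounds == [20]

    def test_plateau_tie_breaks_to_five_prime(self):
        counts = np.array([1, 7, 7, 7, 1.0])
        assert decompose_subpeaks(counts, strand="+")[0] == [1]
        assert decompose_subpeaks(counts, strand="-")[0] == [3]

    def test_min_rel_height_filters_small_peaks(self):
        counts = np.zeros(30)
        counts[5] = 100
        counts[20] = 5  # below 10% of max
        assert decompose_subpeaks(counts)[0] == [5]

    def test_min_separation_merges_close_maxima(self):
        counts = np.zeros(20)
        counts[8] = 100
        counts[10] = 90  # within 5 bp of the taller summit
        assert decompose_subpeaks(counts, min_separation=5)[0] == [8]


def _cluster(counts, g=0.5, chrom="chr1", strand="+", start=0, gene=None):
    counts = np.asarray(counts, dtype=float)
    return TssCluster(
        cluster_id=f"{chrom}:{start}:{strand}:{g}",
        chrom=chrom, strand=strand, start=start, end=start + len(counts),
        summit=start + int(np.argmax(counts)), counts=counts,
        g_fraction=g, gene_id=gene, mitochondrial=chrom in ("chrM", "MT"),
    )


class TestArtifactFilter:
    def test_low_g_removed_high_g_retained(self):
        low = _cluster([10, 50, 10], g=0.05)
        high = _cluster([10, 50, 10], g=0.50, start=100)
        kept = filter_artifact_clusters([low, high])
        assert kept == [high]

    def test_threshold_is_strict_less_than(self):
        at = _cluster([10], g=0.15)
        assert filter_artifact_clusters([at]) == [at]

    def test_missing_g_fraction_is_an_error(self):
        c = _cluster([10], g=0.5)
        c.g_fraction = None
        with pytest.raises(ValueError, match="g_fraction"):
            filter_artifact_clusters([c])

    def test_mitochondrial_exception(self, tmp_path):
        gtf = tmp_path / "m.gtf"
        gtf.write_text(
            'chrM\tx\texon\t101\t200\t.\t+\t.\tgene_id "mg"; transcript_id "mt";\n'
        )
        ann = io.load_annotation(gtf)
        overlapping = _cluster([5, 5], g=0.0, chrom="chrM", start=99)
        elsewhere = _cluster([5, 5], g=0.9, chrom="chrM", start=500)
        kept = filter_artifact_clusters([overlapping, elsewhere], ann)
        assert kept == [overlapping]  # uncapped: G rule waived, overlap required

    def test_idempotent(self):
        clusters = [_cluster([10, 50], g=0.4), _cluster([5], g=0.05, start=99)]
        once = filter_artifact_clusters(clusters)
        assert filter_artifact_clusters(once) == once


class TestMinorIsoformFilter:
    def _pair(self):
        a = _cluster([100], gene="g")
        b = _cluster([9], start=50, gene="g")
        return a, b

    def test_minor_in_all_analyses_dropped(self):
        a, b = self._pair()
        ab = pd.DataFrame({"x": [100, 9], "y": [100, 9]},
                          index=[a.cluster_id, b.cluster_id])
        assert filter_minor_isoforms([a, b], ab) == [a]

    def test_boundary_ten_percent_dropped(self):
        a, b = self._pair()
        ab = pd.DataFrame({"x": [100, 10]}, index=[a.cluster_id, b.cluster_id])
        assert filter_minor_isoforms([a, b], ab) == [a]

    def test_kept_if_above_threshold_in_any_analysis(self):
        a, b = self._pair()
        ab = pd.DataFrame({"x": [100, 9], "y": [100, 50]},
                          index=[a.cluster_id, b.cluster_id])
        assert filter_minor_isoforms([a, b], ab) == [a, b]

    def test_zero_total_gene_dropped_with_warning(self):
        a, b = self._pair()
        ab = pd.DataFrame({"x": [0, 0]}, index=[a.cluster_id, b.cluster_id])
        with pytest.warns(UserWarning, match="zero total"):
            assert filter_minor_isoforms([a, b], ab) == []

    def test_idempotent(self):
        a, b = self._pair()
        ab = pd.DataFrame({"x": [100, 9]}, index=[a.cluster_id, b.cluster_id])
        once = filter_minor_isoforms([a, b], ab)
        assert filter_minor_isoforms(once, ab) == once


class TestFinalizeBoundaries:
    def test_surviving_clusters_partition_each_area(self):
        track = make_track([0, 10, 11, 30, 31, 49], [5, 40, 35, 50, 20, 5])
        areas = call_cluster_areas(track, min_count=10, max_length=200)
        clusters = clusters_from_areas(areas, track)
        final = finalize_boundaries(clusters, areas, track)
        by_area = {}
        for c in final:
            by_area.setdefault(c.area_index, []).append((c.start, c.end))
        for ai, ivs in by_area.items():
            ivs.sort()
            assert ivs[0][0] == areas[ai].start
            assert ivs[-1][1] == areas[ai].end
            assert all(b1 == a2 for (_, b1), (a2, _) in zip(ivs, ivs[1:]))

    def test_single_summit_spans_whole_area(self):
        track = make_track([5, 6, 7], [10, 50, 10])
        areas = call_cluster_areas(track, min_count=10)
        clusters = clusters_from_areas(areas, track)
        final = finalize_boundaries(clusters, areas, track)
        assert len(final) == 1
        assert (final[0].start, final[0].end) == (areas[0].start, areas[0].end)

    def test_midpoint_between_surviving_summits(self):
        # summits at 10 and 30 inside area [0,50): clusters [0,20) and [20,50)
        pos = list(range(50))
        cnt = np.ones(50)
        cnt[10], cnt[30] = 100, 100
        track = make_track(pos, cnt)
        areas = call_cluster_areas(track, min_count=10, max_length=200)
        clusters = clusters_from_areas(areas, track)
        final = finalize_boundaries(clusters, areas, track)
        ivs = sorted((c.start, c.end) for c in final)
        assert ivs == [(0, 20), (20, 50)]

    def test_area_with_no_surviving_summit_dropped(self):
        track = make_track([5], [50])
        areas = call_cluster_areas(track, min_count=10)
        assert finalize_boundaries([], areas, track) == []


class TestGeneAssignment:
    @pytest.fixture()
    def annotation(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr1\tx\texon\t1001\t2000\t.\t+\t.\tgene_id "gp"; transcript_id "tp";\n'
            'chr1\tx\texon\t5001\t6000\t.\t-\t.\tgene_id "gm"; transcript_id "tm";\n'
        )
        return io.load_annotation(gtf)

    def test_within_50bp_upstream_assigned(self, annotation):
        c = _cluster([10], start=970)  # summit 30 bp upstream of locus start
        assert assign_clusters_to_genes([c], annotation)[0].gene_id == "gp"

    def test_beyond_50bp_unassigned(self, annotation):
        c = _cluster([10], start=949)  # 51 bp upstream
        assert assign_clusters_to_genes([c], annotation)[0].gene_id is None

    def test_antisense_summit_unassigned(self, annotation):
        c = _cluster([10], start=1500, strand="-")
        assert assign_clusters_to_genes([c], annotation)[0].gene_id is None

    def test_overlapping_genes_nearest_tss_wins(self, tmp_path):
        gtf = tmp_path / "o.gtf"
        gtf.write_text(
            'chr1\tx\texon\t101\t3000\t.\t+\t.\tgene_id "ga"; transcript_id "ta";\n'
            'chr1\tx\texon\t2001\t5000\t.\t+\t.\tgene_id "gb"; transcript_id "tb";\n'
        )
        ann = io.load_annotation(gtf)
        c = _cluster([10], start=2050)  # inside both; nearest TSS is gb's (2000)
        assert assign_clusters_to_genes([c], ann)[0].gene_id == "gb"


class TestRepresentativeTranscript:
    def _setup(self, tmp_path, utr=30, n_codons=40):
        rng = np.random.default_rng(3)
        codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                  if a + b + c not in ("TAA", "TAG", "TGA")]
        body = "".join(rng.choice(codons, n_codons - 2))
        seq = ("".join(rng.choice(list("ACGT"), utr)) + "ATG" + body + "TAA"
               + "".join(rng.choice(list("ACGT"), 20)))
        genome = {"chr1": "N" * 0 + seq}
        gtf = tmp_path / "r.gtf"
        gtf.write_text(
            f'chr1\tx\texon\t1\t{len(seq)}\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            f'chr1\tx\tCDS\t{utr + 1}\t{utr + 3 * n_codons}\t.\t+\t0\t'
            'gene_id "g"; transcript_id "t";\n'
        )
        return genome, io.load_annotation(gtf), utr, 3 * n_codons

    def test_summit_upstream_keeps_annotated_cds(self, tmp_path):
        genome, ann, utr, _ = self._setup(tmp_path)
        c = _cluster([10], start=5, gene="g")
        assign_representative_transcript(c, ann, genome)
        assert c.transcript_id == "t"
        assert c.cds_start == utr - 5
        assert not c.cds_flagged

    def test_summit_downstream_rescans_in_frame_aug(self, tmp_path):
        genome, ann, utr, cds_len = self._setup(tmp_path)
        seq = genome["chr1"]
        # find the first in-frame ATG strictly inside the CDS
        inframe = [q for q in range(utr + 3, utr + cds_len - 3, 3)
                   if seq[q:q + 3] == "ATG"]
        summit = utr + 6  # 6 nt into the CDS
        c = _cluster([10], start=summit, gene="g")
        assign_representative_transcript(c, ann, genome)
        expected = [q for q in inframe if q >= summit]
        if expected:
            assert c.cds_start == expected[0] - summit
            assert not c.cds_flagged
        else:
            assert c.cds_flagged

    def test_no_downstream_in_frame_aug_flags_cds(self, tmp_path):
        utr = 12
        seq = "A" * utr + "ATG" + "CCA" * 40 + "TAA" + "GGGG"  # no internal ATG
        genome = {"chr1": seq}
        gtf = tmp_path / "n.gtf"
        gtf.write_text(
            f'chr1\tx\texon\t1\t{len(seq)}\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            f'chr1\tx\tCDS\t{utr + 1}\t{utr + 126}\t.\t+\t0\tgene_id "g"; transcript_id "t";\n'
        )
        ann = io.load_annotation(gtf)
        c = _cluster([10], start=utr + 6, gene="g")
        assign_representative_transcript(c, ann, genome)
        assert c.cds_flagged and c.cds_start is None

    def test_isoform_sequence_upstream_extension_is_genomic(self, tmp_path):
        genome, ann, _, _ = self._setup(tmp_path)
        t = ann.transcripts["t"]
        seq, shift = isoform_sequence(0, t, genome)
        assert shift == 0
        assert seq == t.spliced_sequence(genome)


class TestPipelineRecovery:
    def test_recovers_planted_tss_and_drops_artifacts(
        self, small_reference, small_truth, small_tracks
    ):
        from hp5kit.tss_clustering import cluster_tss

        genome, ann = small_reference
        clusters = cluster_tss(small_tracks, ann, genome, assign_transcripts=False)
        summits = {}
        for c in clusters:
            summits.setdefault((c.chrom, c.strand), []).append(c.summit)

        def hit(row):
            return any(abs(s - row["tss"]) <= 5
                       for s in summits.get((row["chrom"], row["strand"]), []))

        capped = small_truth[~small_truth["is_artifact"]]
        artifacts = small_truth[small_truth["is_artifact"]]
        assert capped.apply(hit, axis=1).mean() >= 0.95
        assert artifacts.apply(hit, axis=1).mean() <= 0.05

    def test_clusters_within_gene_do_not_overlap(
        self, small_reference, small_tracks
    ):
        from hp5kit.tss_clustering import cluster_tss

        genome, ann = small_reference
        clusters = cluster_tss(small_tracks, ann, genome, assign_transcripts=False)
        by_gene = {}
        for c in clusters:
            if c.gene_id:
                by_gene.setdefault(c.gene_id, []).append((c.start, c.end))
        for ivs in by_gene.values():
            ivs.sort()
            assert all(b1 <= a2 for (_, b1), (a2, _) in zip(ivs, ivs[1:]))
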