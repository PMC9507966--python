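"""TSS-resolved mRNA features.

Because a TSS is an interval, a feature of "the" isoform is computed at
base resolution and averaged over the cluster extent weighted by per-base
5'-end abundance:

    value = sum_i a_i * v_i / sum_i a_i

where v_i is the feature of the isoform whose 5' end is base i.  Count-like
features (uORF number, TOP start/length, segment lengths) are then rounded
to the nearest integer, a rounded 0 meaning the feature is absent;
continuous scores (Kozak match, structure) are left unrounded.

The structure scorer is a Nussinov maximum base-pairing dynamic program
(Watson-Crick + GU wobble, minimum hairpin loop of 3), reported as the
negated pair count so that, as with folding free energies, more negative
means more structured.  Any callable with the same signature can be
substituted, e.g. a lookup into precomputed folding output.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np
import pandas as pd
from numba import njit

from hp5kit.io import Annotation
from hp5kit.tss_clustering import TssCluster, isoform_sequence

__all__ = [
    "base_weighted_feature",
    "find_uorfs",
    "count_nonoverlapping_uorfs",
    "kozak_match_score",
    "top_motif",
    "structure_score",
    "precomputed_structure_engine",
    "compute_feature_table",
    "expressed_isoforms",
]

_PYRIMIDINES = frozenset("CUTcut")
_RNA_OK = frozenset("ACGUTNacgutn")
_STOPS = frozenset({"UAA", "UAG", "UGA"})


def _rna(seq: str) -> str:
    bad = set(seq) - _RNA_OK
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return seq.upper().replace("T", "U")


def base_weighted_feature(abundance, values, integer: bool = False) -> float:
    """Abundance-weighted mean of per-base feature values over a TSS extent.

    NaN values are excluded together with their weight.  With
    ``integer=True`` the mean is rounded to the nearest integer (half away
    from zero); a rounded 0 is read as absence of the feature.
    """
    a = np.asarray(abundance, dtype=float)
    v = np.asarray(values, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be >= 0")
    ok = ~np.isnan(v)
    w = a[ok]
    if w.sum() <= 0:
        return float("nan")
    mean = float((w * v[ok]).sum() / w.sum())
    if integer:
        return float(np.floor(mean + 0.5)) if mean >= 0 else float(-np.floor(-mean + 0.5))
    return mean


# ---------------------------------------------------------------------------
# uORFs
# ---------------------------------------------------------------------------

def find_uorfs(seq: str, cds_start: int) -> list[tuple[int, int]]:
    """All candidate uORFs: AUG strictly 5' of ``cds_start``, first in-frame
    stop anywhere downstream.  Returns [start, end) nt intervals."""
    s = _rna(seq)
    orfs = []
    for p in range(min(cds_start, len(s) - 2)):
        if s[p : p + 3] != "AUG":
            continue
        q = p + 3
        while q + 3 <= len(s):
            if s[q : q + 3] in _STOPS:
                orfs.append((p, q + 3))
                break
            q += 3
    return orfs


def count_nonoverlapping_uorfs(seq: str, cds_start: int) -> int:
    """Size of a maximum set of non-overlapping uORFs.

    Selected greedily by earliest stop codon (ties -> shorter ORF), the
    classic interval-scheduling rule, which maximizes the count.
    """
    chosen_end = 0
    count = 0
    for start, end in sorted(find_uorfs(seq, cds_start), key=lambda o: (o[1], o[1] - o[0])):
        if start >= chosen_end:
            count += 1
            chosen_end = end
    return count


# ---------------------------------------------------------------------------
# Kozak context
# ---------------------------------------------------------------------------

# consensus gccRccAUGG: offsets relative to the A of AUG; R = purine at -3
_KOZAK_WEIGHTS: tuple[tuple[int, str, float], ...] = (
    (-6, "G", 1.0),
    (-5, "C", 1.0),
    (-4, "C", 1.0),
    (-3, "AG", 3.0),
    (-2, "C", 1.0),
    (-1, "C", 1.0),
    (3, "G", 1.0 * 3.0),
)


def kozak_match_score(seq: str, cds_start: int) -> float:
    """Positional match to the gccRccAUGG consensus, 1.0 for a perfect match.

    The -3 purine and +4 G carry triple weight.  Positions outside the
    sequence (or N) score 0.  Raises if there is no AUG at ``cds_start``.
    """
    s = _rna(seq)
    if s[cds_start : cds_start + 3] != "AUG":
        raise ValueError(f"no AUG at position {cds_start}")
    total = sum(w for _, _, w in _KOZAK_WEIGHTS)
    score = 0.0
    for off, allowed, w in _KOZAK_WEIGHTS:
        p = cds_start + off
        if 0 <= p < len(s) and s[p] in allowed:
            score += w
    return score / total


# ---------------------------------------------------------------------------
# TOP motif
# ---------------------------------------------------------------------------

def top_motif(seq: str) -> tuple[int | None, int]:
    """(1-based position of the 5'-most pyrimidine, run length from there).

    Returns ``(None, 0)`` when the sequence contains no pyrimidine.
    """
    for i, base in enumerate(seq):
        if base in _PYRIMIDINES:
            j = i
            while j < len(seq) and seq[j] in _PYRIMIDINES:
                j += 1
            return i + 1, j - i
    return None, 0


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})
_MIN_LOOP = 3


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
# Watson-Crick + GU wobble on (code_i, code_k)
_PAIR_OK = np.zeros((5, 5), dtype=np.bool_)
for _a, _b in _PAIRS:
    _PAIR_OK[_BASE_CODE[_a], _BASE_CODE[_b]] = True


@njit(cache=False)
def _nussinov_dp(codes, pair_ok, min_loop):  # pragma: no cover - jitted
    n = codes.shape[0]
    dp = np.zeros((n + 2, n + 2), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if pair_ok[codes[i], codes[k]]:
                    v = dp[i + 1, k - 1] + 1 + dp[k + 1, j]
                    if v > best:
                        best = v
            dp[i, j] = best
    return dp[0, n - 1]


def structure_score(seq: str) -> float:
    """Negated Nussinov maximum base-pair count (0 for length < 5)."""
    s = _rna(seq)
    n = len(s)
    if n < _MIN_LOOP + 2:
        return 0.0
    codes = np.array([_BASE_CODE[b] for b in s], dtype=np.int8)
    return -float(_nussinov_dp(codes, _PAIR_OK, _MIN_LOOP))


def precomputed_structure_engine(table: Mapping[str, float]) -> Callable[[str], float]:
    """Structure engine backed by a sequence -> score lookup (e.g. external
    folding output); missing sequences raise."""

    def engine(seq: str) -> float:
        key = _rna(seq)
        if key not in table:
            raise KeyError(f"no precomputed structure score for {key[:30]}...")
        return float(table[key])

    return engine


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

_INT_FEATURES = ("uorf_count", "top_start", "top_length", "utr5_length",
                 "cds_length", "mrna_length")
_FLOAT_FEATURES = ("kozak_score", "structure_cap", "structure_distal")
_CDS_FEATURES = ("uorf_count", "kozak_score", "utr5_length", "cds_length",
                 "structure_distal")


def _base_features(seq: str, cds_start: int | None, cds_end: int | None,
                   cap_window: int, engine) -> dict[str, float]:
    nan = float("nan")
    top_start, top_length = top_motif(seq)
    out = dict(
        mrna_length=float(len(seq)),
        top_start=float(top_start) if top_start is not None else 0.0,
        top_length=float(top_length),
        structure_cap=engine(seq[:cap_window]),
    )
    if cds_start is None:
        out.update({k: nan for k in _CDS_FEATURES})
        return out
    leader = seq[:cds_start]
    out.update(
        uorf_count=float(count_nonoverlapping_uorfs(seq, cds_start)),
        kozak_score=kozak_match_score(seq, cds_start),
        utr5_length=float(cds_start),
        cds_length=float((cds_end or cds_start) - cds_start),
        structure_distal=engine(leader[cap_window:]) if len(leader) > cap_window else 0.0,
    )
    return out


def compute_feature_table(
    clusters: list[TssCluster],
    annotation: Annotation,
    genome,
    cap_window: int = 75,
    structure_engine: Callable[[str], float] | None = None,
) -> pd.DataFrame:
    """One FeatureVector row per TSS cluster, base-weighted over its extent.

    Per-base feature values are computed for the isoform starting at every
    base of the cluster with nonzero 5'-end abundance, through the
    representative transcript's exon structure; the CDS start is rescanned
    per base when the base lies downstream of the annotated AUG.  Clusters
    without a defined CDS get null CDS-dependent fields.
    """
    engine = structure_engine or structure_score
    rows = []
    for c in clusters:
        if c.transcript_id is None:
            continue
        tx = annotation.transcripts[c.transcript_id]
        cds_off = tx.cds_offset()
        cds_len = tx.cds_length()
        bases = np.nonzero(c.counts > 0)[0]
        weights, per_base = [], []
        for off in bases:
            pos = c.start + int(off)
            seq, shift = isoform_sequence(pos, tx, genome)
            if cds_off is not None and cds_len is not None:
                start, end, _ = _shifted_cds(seq, cds_off - shift, cds_len)
            else:
                start = end = None
            per_base.append(_base_features(seq, start, end, cap_window, engine))
            weights.append(float(c.counts[off]))
        if not per_base:
            continue
        row: dict = dict(isoform_id=c.cluster_id, gene_id=c.gene_id,
                         transcript_id=c.transcript_id, chrom=c.chrom)
        for name in _INT_FEATURES + _FLOAT_FEATURES:
            vals = [b[name] for b in per_base]
            row[name] = base_weighted_feature(weights, vals, integer=name in _INT_FEATURES)
        if not np.isnan(row["top_start"]) and row["top_start"] == 0:
            row["top_start"], row["top_length"] = np.nan, 0.0  # rounded to absent
        rows.append(row)
    return pd.DataFrame(rows)


def _shifted_cds(seq: str, new_start: int, cds_len: int):
    """CDS start/end in shifted-isoform coordinates; rescan in-frame AUGs
    when the 5' end lies inside the annotated CDS."""
    stop_off = new_start + cds_len
    if new_start >= 0:
        return new_start, stop_off, False
    q = new_start % 3
    while q + 3 <= stop_off - 3:
        if seq[q : q + 3] == "ATG" or seq[q : q + 3] == "AUG":
            return q, stop_off, True
        q += 3
    return None, None, True


def expressed_isoforms(
    abundances: pd.DataFrame, gene_of: pd.Series, min_relative: float = 0.10
) -> pd.Series:
    """Expressed-isoform flags: abundance strictly greater than
    ``min_relative`` of the gene's most abundant isoform in any condition
    column."""
    genes = gene_of.reindex(abundances.index)
    top = abundances.groupby(genes).transform("max")
    flag = (abundances > min_relative * top).any(axis=1)
    flag.name = "expressed"
    return flag
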