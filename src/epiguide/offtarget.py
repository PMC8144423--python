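"""Genome mismatch search for 23-nt guide+PAM queries and CFD affinity scoring.

The search finds every end-to-end match of a 23-mer (20-nt protospacer plus
NGG PAM) on either genomic strand within a configurable Hamming-distance
budget (default 3, mirroring an exhaustive ``-v 3`` alignment). Mismatches
are counted over the full 23-mer, so PAM-degenerate sites surface as
mismatched hits. The implementation is a pigeonhole seed-and-extend: the
query is cut into four disjoint segments, and with at most three mismatches
at least one segment must match the genome exactly, so exact-segment lookups
in a k-mer index enumerate a complete candidate set which is then verified
by direct Hamming comparison. Completeness is therefore guaranteed by
construction (and cross-checked against a brute-force scan in the tests).

Off-target affinity uses the multiplicative CFD (cutting frequency
determination) model: one penalty factor per mismatched protospacer
position, times a PAM-dinucleotide factor. The penalty tables are supplied
as TSV resources; the bundled default table is a synthetic, clearly-labelled
stand-in so the package works without the published table files, which can
be dropped in via the same TSV interface.
"""

from __future__ import annotations

import importlib.resources
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import TranscriptSet

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GUIDE_LEN = 23  # 20-nt protospacer + 3-nt PAM
_SEED_LEN = 5
# Disjoint segments covering the 23-mer; with <= 3 mismatches at least one
# segment is an exact match (pigeonhole over 4 parts).
_SEGMENTS = ((0, 6), (6, 12), (12, 18), (18, 23))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class OffTargetHit:
    chrom: str
    start: int  # 0-based start of the 23-mer window on the plus strand
    strand: str
    matched: str  # 23-mer in guide orientation
    n_mismatches: int
    context: str | None = None  # exonic / intronic / intergenic
    cfd: float | None = None

    def classified(self, context: str, cfd: float) -> "OffTargetHit":
        return OffTargetHit(self.chrom, self.start, self.strand, self.matched,
                            self.n_mismatches, context, cfd)


@dataclass
class OffTargetPolicy:
    """Enumeration and filtering thresholds for the off-target search."""

    max_mismatches: int = 3
    max_reported: int = 35
    drop_if_exact_matches_gt: int = 1
    drop_if_alignments_gt: int = 25

    def __post_init__(self):
        if self.max_mismatches < 0 or min(
                self.max_reported, self.drop_if_exact_matches_gt,
                self.drop_if_alignments_gt) < 1:
            raise ValueError("policy thresholds must be positive")
        if self.max_reported < self.drop_if_alignments_gt:
            raise ValueError("max_reported must be >= drop_if_alignments_gt")


class GenomeIndex:
    """In-memory genome with a k-mer seed index for the mismatch search."""

    def __init__(self, sequences: dict[str, str]):
        if len(set(sequences)) != len(sequences):
            raise ValueError("duplicate chromosome names")
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        self._seed_index: dict[str, list[tuple[str, int]]] | None = None

    @classmethod
    def from_fasta(cls, path) -> "GenomeIndex":
        from .io import read_fasta

        return cls(read_fasta(path))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.sequences[chrom][start:end]
        return seq if strand == "+" else revcomp(seq)

    def _seeds(self) -> dict[str, list[tuple[str, int]]]:
        if self._seed_index is None:
            index: dict[str, list[tuple[str, int]]] = {}
            for chrom, seq in sorted(self.sequences.items()):
                for i in range(len(seq) - _SEED_LEN + 1):
                    index.setdefault(seq[i:i + _SEED_LEN], []).append((chrom, i))
            self._seed_index = index
        return self._seed_index


def index_genome(sequences: dict[str, str] | Iterable) -> GenomeIndex:
    """Build a :class:`GenomeIndex` from {name: sequence} or FASTA records."""
    if not isinstance(sequences, dict):
        records = list(sequences)
        names = [rec.id for rec in records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        sequences = {rec.id: str(rec.seq) for rec in records}
    return GenomeIndex(sequences)


def _candidate_starts(query: str, index: GenomeIndex) -> set[tuple[str, int]]:
    seeds = index._seeds()
    out: set[tuple[str, int]] = set()
    for seg_start, _seg_end in _SEGMENTS:
        seed = query[seg_start:seg_start + _SEED_LEN]
        for chrom, pos in seeds.get(seed, ()):
            start = pos - seg_start
            if start >= 0 and start + GUIDE_LEN <= index.chrom_length(chrom):
                out.add((chrom, start))
    return out


def find_off_targets(guide23: str, index: GenomeIndex,
                     policy: OffTargetPolicy | None = None) -> list[OffTargetHit]:
    """All end-to-end genomic matches of guide23 within the mismatch budget.

    Both strands are searched; minus-strand hits report the plus-strand
    window start and the matched sequence in guide orientation. The hit list
    is sorted by (chrom, start, strand) and truncated deterministically at
    ``policy.max_reported``.
    """
    policy = policy or OffTargetPolicy()
    guide23 = guide23.upper()
    if len(guide23) != GUIDE_LEN:
        raise ValueError(f"guide23 must be {GUIDE_LEN} nt, got {len(guide23)}")
    if "N" in guide23:
        raise ValueError("guide23 must not contain N")

    hits: list[OffTargetHit] = []
    for strand, query in (("+", guide23), ("-", revcomp(guide23))):
        for chrom, start in _candidate_starts(query, index):
            window = index.sequences[chrom][start:start + GUIDE_LEN]
            d = hamming(query, window)
            if d <= policy.max_mismatches:
                matched = window if strand == "+" else revcomp(window)
                hits.append(OffTargetHit(chrom, start, strand, matched, d))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits[: policy.max_reported]


def apply_offtarget_filters(
    guide23: str,
    hits: Sequence[OffTargetHit],
    policy: OffTargetPolicy | None = None,
    on_target: tuple[str, int, str] | None = None,
) -> tuple[bool, list[OffTargetHit]]:
    """Keep/drop decision for a guide given its full hit list (on-target included).

    Drops guides with more than one exact genomic match (duplicated region)
    or with more alignments than the policy allows. For kept guides the
    on-target site — identified by ``on_target = (chrom, start, strand)``
    when given, else the unique exact match — is removed from the retained
    hits before scorecard construction.
    """
    policy = policy or OffTargetPolicy()
    exact = [h for h in hits if h.n_mismatches == 0]
    if len(exact) > policy.drop_if_exact_matches_gt:
        return False, []
    if len(hits) > policy.drop_if_alignments_gt:
        return False, []

    def is_on_target(h: OffTargetHit) -> bool:
        if on_target is not None:
            return (h.chrom, h.start, h.strand) == on_target
        return h.n_mismatches == 0

    return True, [h for h in hits if not is_on_target(h)]


def classify_context(hit: OffTargetHit, transcripts: TranscriptSet) -> str:
    """exonic if the hit overlaps any exon, intronic if inside a transcript
    span, intergenic otherwise; overlap on either strand counts."""
    start, end = hit.start, hit.start + GUIDE_LEN
    if transcripts.overlaps_exon(hit.chrom, start, end):
        return "exonic"
    if transcripts.overlapping_transcripts(hit.chrom, start, end):
        return "intronic"
    return "intergenic"


# ---------------------------------------------------------------------------
# CFD scoring

@dataclass
class CfdTable:
    """Multiplicative mismatch/PAM penalties for the CFD off-target model.

    mismatch: {(position 1-20, guide_base, target_base): penalty}; matched
    bases implicitly contribute 1. pam: {dinucleotide: penalty} keyed by the
    last two bases of the target site's PAM.
    """

    mismatch: dict[tuple[int, str, str], float]
    pam: dict[str, float]

    def __post_init__(self):
        for key, v in self.mismatch.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"mismatch penalty out of [0,1] at {key}: {v}")
        for key, v in self.pam.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"PAM penalty out of [0,1] at {key}: {v}")

    @classmethod
    def from_tsv(cls, mismatch_path, pam_path) -> "CfdTable":
        mismatch: dict[tuple[int, str, str], float] = {}
        with open(mismatch_path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] == "position":
                    continue
                pos, gb, tb, pen = parts
                mismatch[(int(pos), gb, tb)] = float(pen)
        pam: dict[str, float] = {}
        with open(pam_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] == "dinucleotide":
                    continue
                pam[parts[0]] = float(parts[1])
        return cls(mismatch, pam)

    @classmethod
    def synthetic_default(cls) -> "CfdTable":
        """The bundled synthetic penalty table (a documented stand-in, not
        the published CFD values)."""
        res = importlib.resources.files("epiguide") / "resources"
        return cls.from_tsv(
            os.fspath(res / "cfd_synthetic_mismatch.tsv"),
            os.fspath(res / "cfd_synthetic_pam.tsv"),
        )


def cfd_score(guide23: str, matched23: str, table: CfdTable) -> float:
    """Product of per-position mismatch penalties over the 20-nt protospacer,
    times the PAM-dinucleotide penalty of the matched site."""
    if len(guide23) != GUIDE_LEN or len(matched23) != GUIDE_LEN:
        raise ValueError("both sequences must be 23 nt")
    score = 1.0
    for pos in range(20):
        g, t = guide23[pos], matched23[pos]
        if g == t:
            continue
        key = (pos + 1, g, t)
        try:
            score *= table.mismatch[key]
        except KeyError:
            raise KeyError(f"no CFD penalty for (position={pos + 1}, "
                           f"guide_base={g!r}, target_base={t!r})") from None
    dinuc = matched23[21:23]
    try:
        score *= table.pam[dinuc]
    except KeyError:
        raise KeyError(f"no CFD PAM penalty for dinucleotide {dinuc!r}") from None
    return score


def annotate_hits(guide23: str, hits: Sequence[OffTargetHit],
                  transcripts: TranscriptSet, table: CfdTable) -> list[OffTargetHit]:
    """Attach genomic context class and CFD affinity to each hit."""
    return [h.classified(classify_context(h, transcripts),
                         cfd_score(guide23, h.matched, table)) for h in hits]
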