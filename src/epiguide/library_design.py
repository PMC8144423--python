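"""Domain-focused sgRNA library design.

The design procedure targets functional protein domains rather than whole
coding sequences: domain intervals (with a manually assigned importance
category) are intersected with transcript annotations, candidate guides are
enumerated at every NGG PAM inside a domain, each candidate is scored for
predicted on-target efficiency and for its genome-wide off-target profile,
and guides are ranked per gene by the mean of seven component ranks. The
final selection prefers guides in higher-priority domain categories
(catalytic first by default) and keeps the k best per gene. Selected guides
are emitted as 60-nt array-synthesis oligos: a 20-nt G-starting sgRNA
flanked on each side by a 20-nt arm carrying a BsmBI (CGTCTC) recognition
site for Golden-Gate cloning.

Sequence conventions: the 30-nt scoring context is 4 nt upstream + 20-nt
protospacer + NGG PAM + 3 nt downstream, in protospacer orientation; the
23-mer used for off-target search is protospacer + PAM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import BedRecord, TranscriptSet
from .offtarget import GenomeIndex, OffTargetHit, revcomp

log = logging.getLogger("epiguide")

CATEGORIES = ("catalytic", "reader", "dna_binding", "protein_interaction", "other")
BSMBI_SITE = "CGTCTC"

# Default cloning arms: 20 nt each, each carrying a BsmBI recognition site
# (on the minus strand in the left arm) so the sgRNA drops out on digestion.
DEFAULT_FLANK_LEFT = "TGTATGAGACGCGTATGCTG"
DEFAULT_FLANK_RIGHT = "GTTTCGTCTCACTGGAGCAC"


def _has_bsmbi(seq: str) -> bool:
    return BSMBI_SITE in seq or BSMBI_SITE in revcomp(seq)


@dataclass(frozen=True)
class DomainInterval:
    gene_id: str
    domain_name: str
    category: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    transcript_ids: tuple[str, ...]

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.domain_name}: start >= end")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.domain_name}: unknown category {self.category!r}")


@dataclass(frozen=True)
class CandidateGuide:
    protospacer: str   # 20 nt, genomic sequence in guide orientation
    context30: str     # 4 + 20 + PAM(3) + 3
    guide23: str       # protospacer + PAM
    chrom: str
    cut_position: int  # genomic coordinate of the blunt cut, 3 bp 5' of PAM
    strand: str
    gene_id: str
    domain_name: str
    category: str
    start: int         # genomic start of the protospacer (plus-strand coords)

    def __post_init__(self):
        assert len(self.protospacer) == 20
        assert len(self.context30) == 30
        assert self.context30[4:24] == self.protospacer
        assert self.context30[25:27] == "GG"
        assert self.guide23 == self.protospacer + self.context30[24:27]


@dataclass
class GuideScorecard:
    """Per-guide ranking inputs: on-target efficiency plus off-target
    counts and maximum CFD affinity in each genomic context class."""

    candidate: CandidateGuide
    on_target_score: float
    n_exonic_ot: int = 0
    n_intronic_ot: int = 0
    n_intergenic_ot: int = 0
    max_cfd_exonic: float = 0.0
    max_cfd_intronic: float = 0.0
    max_cfd_intergenic: float = 0.0
    rank_score: float | None = None

    def criteria(self) -> tuple:
        return (self.on_target_score, self.n_exonic_ot, self.max_cfd_exonic,
                self.n_intronic_ot, self.max_cfd_intronic,
                self.n_intergenic_ot, self.max_cfd_intergenic)


@dataclass(frozen=True)
class OligoRecord:
    sequence: str  # 60 nt
    guide_id: str
    gene_id: str   # or "non-targeting" / the positive-control gene

    def __post_init__(self):
        if len(self.sequence) != 60:
            raise ValueError(f"{self.guide_id}: oligo is {len(self.sequence)} nt")
        sg = self.sequence[20:40]
        if not sg.startswith("G"):
            raise ValueError(f"{self.guide_id}: sgRNA does not start with G")
        if not (_has_bsmbi(self.sequence[:20]) and _has_bsmbi(self.sequence[40:])):
            raise ValueError(f"{self.guide_id}: flank lacks BsmBI site")


@dataclass
class DesignConfig:
    guides_per_gene_k: int = 11
    domain_priority: tuple[str, ...] = CATEGORIES
    lowcomplexity_min_run: int = 8
    require_genomic_5prime_G: bool = True
    flank_left: str = DEFAULT_FLANK_LEFT
    flank_right: str = DEFAULT_FLANK_RIGHT
    on_target_scorer: dict = field(default_factory=lambda: {"name": "position_weight"})

    def __post_init__(self):
        if not 1 <= self.guides_per_gene_k <= 50:
            raise ValueError("guides_per_gene_k must be in 1..50")
        self.domain_priority = tuple(self.domain_priority)
        if sorted(self.domain_priority) != sorted(CATEGORIES):
            raise ValueError("domain_priority must order the five categories")
        for name, flank in (("flank_left", self.flank_left),
                            ("flank_right", self.flank_right)):
            if len(flank) != 20:
                raise ValueError(f"{name} must be 20 nt")
            if not _has_bsmbi(flank):
                raise ValueError(f"{name} lacks a BsmBI ({BSMBI_SITE}) site")


# ---------------------------------------------------------------------------
# Domain loading

def load_domain_intervals(
    domains: Sequence[BedRecord],
    category_map: Mapping[str, str],
    transcripts: TranscriptSet,
    genome: GenomeIndex | None = None,
) -> list[DomainInterval]:
    """Intersect domain intervals with transcripts and annotate them.

    Domains overlapping no transcript are dropped. Domains on chromosomes
    absent from the genome (when one is supplied) are skipped with a
    warning. Unmapped domain names get category "other". The gene_id is
    taken from the first overlapping transcript (sorted by id).
    """
    out: list[DomainInterval] = []
    for rec in domains:
        if genome is not None and rec.chrom not in genome:
            log.warning("domain %s: chromosome %s absent from genome, skipped",
                        rec.name, rec.chrom)
            continue
        tids = transcripts.overlapping_transcripts(rec.chrom, rec.start, rec.end)
        if not tids:
            continue
        category = category_map.get(rec.name, "other")
        out.append(DomainInterval(
            gene_id=transcripts.gene_of(tids[0]),
            domain_name=rec.name,
            category=category,
            chrom=rec.chrom,
            start=rec.start,
            end=rec.end,
            strand=rec.strand,
            transcript_ids=tuple(tids),
        ))
    return out


# ---------------------------------------------------------------------------
# Candidate extraction

def _homopolymer_runs(seq: str, min_run: int) -> list[tuple[int, int]]:
    """Half-open [start, end) spans of homopolymer runs of length >= min_run."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j))
        i = j
    return runs


def extract_candidates(genome: GenomeIndex, interval: DomainInterval,
                       cfg: DesignConfig | None = None) -> list[CandidateGuide]:
    """Enumerate candidate guides at every NGG PAM inside the interval.

    Both strands are scanned; the 23-mer (protospacer + PAM) must lie fully
    inside the interval while the 30-nt context may extend into the
    flanking chromosome sequence. Candidates are excluded when the context
    runs off a chromosome end, contains N, the protospacer overlaps a
    homopolymer run of at least ``lowcomplexity_min_run`` bases (the
    low-complexity trim), or — under the default 5'-G requirement — the
    genomic protospacer does not start with G.
    """
    cfg = cfg or DesignConfig()
    chrom_seq = genome.sequences[interval.chrom]
    a, b = interval.start, interval.end
    if b - a < 23:
        return []
    runs = [(a + s, a + e)
            for s, e in _homopolymer_runs(chrom_seq[a:b], cfg.lowcomplexity_min_run)]

    def in_lowcomplexity(ps_start: int, ps_end: int) -> bool:
        return any(ps_start < re and rs < ps_end for rs, re in runs)

    out: list[CandidateGuide] = []
    # plus strand: protospacer [s, s+20), PAM [s+20, s+23) with GG at s+21
    for s in range(a, b - 22):
        if chrom_seq[s + 21:s + 23] != "GG":
            continue
        if s - 4 < 0 or s + 26 > len(chrom_seq):
            continue
        context = chrom_seq[s - 4:s + 26]
        if "N" in context:
            continue
        if in_lowcomplexity(s, s + 20):
            continue
        protospacer = context[4:24]
        if cfg.require_genomic_5prime_G and not protospacer.startswith("G"):
            continue
        out.append(CandidateGuide(
            protospacer=protospacer, context30=context,
            guide23=context[4:27], chrom=interval.chrom,
            cut_position=s + 17, strand="+",
            gene_id=interval.gene_id, domain_name=interval.domain_name,
            category=interval.category, start=s,
        ))
    # minus strand: plus-strand CCN at [t-3, t), protospacer revcomp of [t, t+20)
    for t in range(a + 3, b - 19):
        if chrom_seq[t - 3:t - 1] != "CC":
            continue
        if t - 6 < 0 or t + 24 > len(chrom_seq):
            continue
        context = revcomp(chrom_seq[t - 6:t + 24])
        if "N" in context:
            continue
        if in_lowcomplexity(t, t + 20):
            continue
        protospacer = context[4:24]
        if cfg.require_genomic_5prime_G and not protospacer.startswith("G"):
            continue
        out.append(CandidateGuide(
            protospacer=protospacer, context30=context,
            guide23=context[4:27], chrom=interval.chrom,
            cut_position=t + 3, strand="-",
            gene_id=interval.gene_id, domain_name=interval.domain_name,
            category=interval.category, start=t,
        ))
    out.sort(key=lambda c: (c.start, c.strand))
    return out


# ---------------------------------------------------------------------------
# On-target scoring

class PositionWeightScorer:
    """Deterministic position-weight surrogate for on-target efficiency.

    This is a documented stand-in, not a trained efficiency model: the
    score is the logistic squash of a sum of per-(position, base) weights
    over the 30-nt context. Precomputed scores from any external model can
    be supplied instead via :class:`PrecomputedScorer`.
    """

    # Mild heuristic defaults: reward G adjacent to the PAM and moderate GC
    # in the seed region; zero elsewhere.
    DEFAULT_WEIGHTS = {
        (23, "G"): 0.6, (23, "C"): 0.2, (23, "T"): -0.3,
        (19, "G"): 0.2, (19, "C"): 0.2,
        (4, "G"): 0.2,
        (27, "G"): -0.2,
    }

    def __init__(self, weights: Mapping[tuple[int, str], float] | None = None):
        self.weights = dict(self.DEFAULT_WEIGHTS if weights is None else weights)

    def __call__(self, context30: str) -> float:
        if len(context30) != 30:
            raise ValueError("context must be 30 nt")
        if "N" in context30:
            raise ValueError("on-target score undefined for context containing N")
        total = sum(self.weights.get((i, base), 0.0)
                    for i, base in enumerate(context30))
        return float(1.0 / (1.0 + np.exp(-total)))


class PrecomputedScorer:
    """Scores looked up from an external model's output (context -> score)."""

    def __init__(self, scores: Mapping[str, float]):
        self.scores = dict(scores)

    @classmethod
    def from_tsv(cls, path, key_column: str = "context30",
                 score_column: str = "score") -> "PrecomputedScorer":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df[key_column], df[score_column].astype(float))))

    def __call__(self, context30: str) -> float:
        if "N" in context30:
            raise ValueError("on-target score undefined for context containing N")
        return self.scores[context30]


def get_scorer(spec: Mapping | None):
    spec = dict(spec or {"name": "position_weight"})
    name = spec.get("name", "position_weight")
    if name == "position_weight":
        weights = spec.get("weights")
        if weights is not None:
            weights = {(int(p), b): float(w)
                       for (p, b), w in
                       ((tuple(k.split(":")) if isinstance(k, str) else k, v)
                        for k, v in weights.items())}
        return PositionWeightScorer(weights)
    if name == "precomputed":
        return PrecomputedScorer.from_tsv(spec["path"],
                                          spec.get("key_column", "context30"),
                                          spec.get("score_column", "score"))
    raise ValueError(f"unknown on-target scorer {name!r}")


def score_on_target(candidate: CandidateGuide, scorer) -> float:
    if callable(scorer):
        return scorer(candidate.context30)
    return get_scorer(scorer)(candidate.context30)


# ---------------------------------------------------------------------------
# Scorecards, ranking, selection

def build_scorecard(candidate: CandidateGuide, hits: Sequence[OffTargetHit],
                    on_target: float) -> GuideScorecard:
    """Tally classified off-target hits (on-target site already removed)."""
    card = GuideScorecard(candidate=candidate, on_target_score=on_target)
    for h in hits:
        if h.context is None or h.cfd is None:
            raise ValueError("hit lacks context/CFD annotation")
        if h.context == "exonic":
            card.n_exonic_ot += 1
            card.max_cfd_exonic = max(card.max_cfd_exonic, h.cfd)
        elif h.context == "intronic":
            card.n_intronic_ot += 1
            card.max_cfd_intronic = max(card.max_cfd_intronic, h.cfd)
        elif h.context == "intergenic":
            card.n_intergenic_ot += 1
            card.max_cfd_intergenic = max(card.max_cfd_intergenic, h.cfd)
        else:
            raise ValueError(f"unknown context {h.context!r}")
    return card


def rank_guides(scorecards: Sequence[GuideScorecard]) -> list[GuideScorecard]:
    """Mean-of-ranks aggregation over the seven component criteria.

    On-target efficiency is ranked descending (best = rank 1); the six
    off-target criteria ascending (fewer hits / lower affinity = rank 1).
    Ties receive the average of the tied ranks. Returns the scorecards
    sorted by ascending rank_score, ties broken by higher on-target score
    then lexicographic protospacer.
    """
    if not scorecards:
        raise ValueError("no scorecards to rank")
    for c in scorecards:
        if c.on_target_score is None:
            raise ValueError("scorecard with unset on-target score")
    crit = np.array([c.criteria() for c in scorecards], dtype=float)
    ranks = np.empty_like(crit)
    ranks[:, 0] = rankdata(-crit[:, 0], method="average")  # on-target: descending
    for j in range(1, 7):
        ranks[:, j] = rankdata(crit[:, j], method="average")
    for card, score in zip(scorecards, ranks.mean(axis=1)):
        card.rank_score = float(score)
    return sorted(scorecards,
                  key=lambda c: (c.rank_score, -c.on_target_score,
                                 c.candidate.protospacer))


def select_guides(ranked: Mapping[str, Sequence[GuideScorecard]],
                  cfg: DesignConfig | None = None
                  ) -> dict[str, list[GuideScorecard]]:
    """Per-gene selection: sort by domain-category priority then rank score,
    keep the top k (all candidates when a gene has fewer than k)."""
    cfg = cfg or DesignConfig()
    priority = {cat: i for i, cat in enumerate(cfg.domain_priority)}
    out: dict[str, list[GuideScorecard]] = {}
    for gene, cards in ranked.items():
        for c in cards:
            if c.candidate.category not in priority:
                raise ValueError(
                    f"guide {c.candidate.protospacer} (gene {gene}): "
                    f"unknown category {c.candidate.category!r}")
            if c.rank_score is None:
                raise ValueError(f"guide {c.candidate.protospacer}: unranked")
        ordered = sorted(cards, key=lambda c: (
            priority[c.candidate.category], c.rank_score,
            -c.on_target_score, c.candidate.protospacer))
        out[gene] = list(ordered[:cfg.guides_per_gene_k])
    return out


# ---------------------------------------------------------------------------
# Oligo and library assembly

def _as_sgrna(protospacer: str, cfg: DesignConfig) -> str:
    if protospacer.startswith("G"):
        return protospacer
    if cfg.require_genomic_5prime_G:
        raise ValueError(
            f"protospacer {protospacer} does not start with G and "
            "5'-G substitution is disabled")
    return "G" + protospacer[1:]


def build_oligo(guide, cfg: DesignConfig | None = None,
                guide_id: str | None = None, gene_id: str | None = None
                ) -> OligoRecord:
    """60-nt synthesis oligo: left arm + 20-nt G-starting sgRNA + right arm.

    Accepts a :class:`GuideScorecard`, :class:`CandidateGuide` or a bare
    20-nt protospacer string (the latter — used for control guides — always
    gets a substituted 5' G when needed).
    """
    cfg = cfg or DesignConfig()
    if isinstance(guide, GuideScorecard):
        guide = guide.candidate
    if isinstance(guide, CandidateGuide):
        sgrna = _as_sgrna(guide.protospacer, cfg)
        gene_id = gene_id or guide.gene_id
    else:
        if len(guide) != 20:
            raise ValueError("protospacer must be 20 nt")
        sgrna = guide if guide.startswith("G") else "G" + guide[1:]
    return OligoRecord(cfg.flank_left + sgrna + cfg.flank_right,
                       guide_id or "guide", gene_id or "unknown")


def assemble_library(
    selections: Mapping[str, Sequence[GuideScorecard]],
    non_targeting: Sequence[str],
    positive_controls: Mapping[str, Sequence[str]],
    cfg: DesignConfig | None = None,
) -> pd.DataFrame:
    """Assemble the final library table (one row per synthesized oligo).

    Raises on duplicate protospacers anywhere in the union; logs the
    non-targeting fraction of the assembled library.
    """
    cfg = cfg or DesignConfig()
    rows = []
    for gene in sorted(selections):
        for i, card in enumerate(selections[gene], start=1):
            cand = card.candidate
            sgrna = _as_sgrna(cand.protospacer, cfg)
            gid = f"{gene}_{cand.domain_name}_{i:02d}"
            oligo = build_oligo(card, cfg, guide_id=gid)
            rows.append((gid, gene, cand.domain_name, cand.category,
                         "targeting", sgrna, oligo.sequence))
    for gene in sorted(positive_controls):
        for i, ps in enumerate(positive_controls[gene], start=1):
            gid = f"{gene}_pc_{i:02d}"
            oligo = build_oligo(ps, cfg, guide_id=gid, gene_id=gene)
            rows.append((gid, gene, "positive_control", "other",
                         "positive_control", oligo.sequence[20:40], oligo.sequence))
    for i, ps in enumerate(non_targeting, start=1):
        gid = f"NT_{i:04d}"
        oligo = build_oligo(ps, cfg, guide_id=gid, gene_id="non-targeting")
        rows.append((gid, "non-targeting", "non_targeting", "other",
                     "non_targeting", oligo.sequence[20:40], oligo.sequence))

    df = pd.DataFrame(rows, columns=["guide_id", "gene_id", "domain_name",
                                     "category", "role", "protospacer", "oligo"])
    dup = df["protospacer"][df["protospacer"].duplicated(keep=False)]
    if len(dup):
        collisions = {ps: sorted(df.loc[df["protospacer"] == ps, "guide_id"])
                      for ps in sorted(set(dup))}
        raise ValueError(f"duplicate protospacers across library: {collisions}")
    frac = (df["role"] == "non_targeting").mean()
    log.info("assembled library: %d oligos, non-targeting fraction %.3f",
             len(df), frac)
    return df


def library_composition(df: pd.DataFrame) -> dict:
    """Audit summary of a library table: totals per role and the category
    percentage breakdown of targeting guides."""
    targeting = df[df["role"] == "targeting"]
    by_cat = (targeting["category"].value_counts(normalize=True) * 100).round(1)
    return {
        "total": int(len(df)),
        "targeting": int((df["role"] == "targeting").sum()),
        "non_targeting": int((df["role"] == "non_targeting").sum()),
        "positive_control": int((df["role"] == "positive_control").sum()),
        "non_targeting_pct": round(float((df["role"] == "non_targeting").mean() * 100), 1),
        "category_pct": {k: float(v) for k, v in by_cat.items()},
        "n_genes": int(targeting["gene_id"].nunique()),
    }
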