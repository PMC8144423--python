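"""End-to-end library design: domains -> candidates -> off-target profiling
-> ranking -> domain-priority selection -> oligo library table."""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .io import BedRecord, TranscriptSet
from .library_design import (CandidateGuide, DesignConfig, GuideScorecard,
                             assemble_library, build_scorecard,
                             extract_candidates, get_scorer,
                             load_domain_intervals, rank_guides, select_guides)
from .offtarget import (CfdTable, GenomeIndex, OffTargetPolicy, annotate_hits,
                        apply_offtarget_filters, find_off_targets)

log = logging.getLogger("epiguide")


def on_target_locus(cand: CandidateGuide) -> tuple[str, int, str]:
    """(chrom, 23-mer window start, strand) of the design site itself."""
    start = cand.start if cand.strand == "+" else cand.start - 3
    return (cand.chrom, start, cand.strand)


def design_library(
    genome: GenomeIndex,
    transcripts: TranscriptSet,
    domains: Sequence[BedRecord],
    category_map: Mapping[str, str],
    cfg: DesignConfig | None = None,
    policy: OffTargetPolicy | None = None,
    cfd: CfdTable | None = None,
    non_targeting: Sequence[str] = (),
    positive_controls: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Run the whole design procedure and return the library table.

    Guides failing the off-target policy (duplicated genomic region or too
    many alignments) are discarded before ranking; ranking and selection
    are per gene across all of its domains.
    """
    cfg = cfg or DesignConfig()
    policy = policy or OffTargetPolicy()
    cfd = cfd or CfdTable.synthetic_default()
    scorer = get_scorer(cfg.on_target_scorer)

    intervals = load_domain_intervals(domains, category_map, transcripts, genome)
    log.info("design: %d domain intervals after transcript intersection",
             len(intervals))
    by_gene: dict[str, list[GuideScorecard]] = {}
    n_candidates = n_dropped = 0
    for interval in intervals:
        for cand in extract_candidates(genome, interval, cfg):
            n_candidates += 1
            hits = find_off_targets(cand.guide23, genome, policy)
            keep, retained = apply_offtarget_filters(
                cand.guide23, hits, policy, on_target=on_target_locus(cand))
            if not keep:
                n_dropped += 1
                continue
            annotated = annotate_hits(cand.guide23, retained, transcripts, cfd)
            card = build_scorecard(cand, annotated, scorer(cand.context30))
            by_gene.setdefault(cand.gene_id, []).append(card)
    log.info("design: %d candidates, %d dropped by off-target policy",
             n_candidates, n_dropped)

    ranked = {gene: rank_guides(cards) for gene, cards in sorted(by_gene.items())}
    selections = select_guides(ranked, cfg)
    return assemble_library(selections, list(non_targeting),
                            dict(positive_controls or {}), cfg)
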