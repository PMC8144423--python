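"""Pooled dropout-screen analysis: counting, normalization, fold changes,
hit calling, gene-set comparison, and the auxiliary rule-based filters.

The analysis follows the classic negative-selection recipe: reads (or a
count table) are mapped to the guide library, each sample is normalized by
its mean count so sequencing depth cancels, guides that start in the lowest
2nd percentile of any reference-timepoint sample are removed, normalized
counts are averaged across the two biological replicates, and per-guide
fold changes later/reference are computed with a small symmetric
pseudocount. A gene is a hit when at least ``min_depleted_guides`` of its
guides are depleted at least ``hit_fold_threshold``-fold (fc <= 1/threshold,
boundary inclusive) at the final timepoint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix

log = logging.getLogger("epiguide")


@dataclass
class ScreenConfig:
    low_percentile: float = 2.0          # percent; lowest tail removed at reference
    pseudocount: float = 0.5             # in read-count units; see pipeline note
    hit_fold_threshold: float = 10.0     # "10-fold depleted"
    min_depleted_guides: int = 1
    reference_timepoint: str = "day1"
    hit_timepoint: str = "day11"
    read_guide_offset: int = 0           # start of the 20-nt guide region in a read

    def __post_init__(self):
        if not 0 < self.low_percentile < 100:
            raise ValueError("low_percentile must be in (0, 100)")
        if self.hit_fold_threshold <= 1:
            raise ValueError("hit_fold_threshold must be > 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


# ---------------------------------------------------------------------------
# Read counting

def _single_mismatch_variants(seq: str):
    for i, base in enumerate(seq):
        for alt in "ACGT":
            if alt != base:
                yield seq[:i] + alt + seq[i + 1:]


def count_reads(reads: Iterable[str], library: pd.DataFrame,
                cfg: ScreenConfig | None = None) -> pd.Series:
    """Assign reads to library guides with at most one mismatch.

    A read's guide region (20 nt at ``read_guide_offset``) is matched
    against the library protospacers; exact matches win over one-mismatch
    matches, and a read matching more than one guide at its best stratum is
    discarded (unique-mapping rule). Returns integer counts per guide_id.
    """
    cfg = cfg or ScreenConfig()
    if len(library) == 0:
        raise ValueError("empty library")
    exact = {}
    for gid, ps in zip(library["guide_id"], library["protospacer"]):
        exact.setdefault(ps, []).append(gid)
    counts = pd.Series(0, index=library["guide_id"], dtype=int)
    off = cfg.read_guide_offset
    for read in reads:
        region = str(read)[off:off + 20].upper()
        if len(region) < 20:
            continue
        best = exact.get(region, [])
        if not best:
            one_mm = [gid for var in _single_mismatch_variants(region)
                      for gid in exact.get(var, [])]
            best = one_mm
        if len(best) == 1:
            counts[best[0]] += 1
    return counts


def read_fastq_sequences(path) -> Iterable[str]:
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        yield str(rec.seq)


# ---------------------------------------------------------------------------
# Normalization and filtering

def normalize_counts(cm: CountMatrix) -> CountMatrix:
    """Divide each sample's counts by that sample's mean count."""
    means = cm.counts.mean(axis=0)
    zero = means.index[means == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero)}")
    out = CountMatrix.__new__(CountMatrix)  # skip integer validation
    out.counts = cm.counts / means
    out.samples = cm.samples
    return out


def nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank empirical percentile: the ceil(p/100 * n)-th smallest."""
    v = np.sort(np.asarray(values, dtype=float))
    k = max(1, math.ceil(pct / 100.0 * len(v)))
    return float(v[k - 1])


def filter_low_abundance(cm: CountMatrix, cfg: ScreenConfig | None = None
                         ) -> tuple[CountMatrix, list[str]]:
    """Remove guides in the lowest tail of any reference-timepoint sample.

    A guide is removed if its value in any reference sample is <= the
    nearest-rank ``low_percentile`` of that sample. A sample whose values
    are all identical contributes no removals (the <= rule would otherwise
    degenerate to removing everything).
    """
    cfg = cfg or ScreenConfig()
    ref_samples = cm.samples_at(cfg.reference_timepoint)
    if not ref_samples:
        raise ValueError(f"no samples at reference timepoint "
                         f"{cfg.reference_timepoint!r}")
    removed: set[str] = set()
    for s in ref_samples:
        col = cm.counts[s].to_numpy(dtype=float)
        if np.all(col == col[0]):
            continue
        thr = nearest_rank_percentile(col, cfg.low_percentile)
        removed.update(cm.counts.index[col <= thr])
    keep = [g for g in cm.counts.index if g not in removed]
    out = CountMatrix.__new__(CountMatrix)
    out.counts = cm.counts.loc[keep]
    out.samples = cm.samples
    return out, sorted(removed)


# ---------------------------------------------------------------------------
# Fold changes and hit calling

def compute_fold_changes(cm: CountMatrix, library: pd.DataFrame | None = None,
                         cfg: ScreenConfig | None = None) -> pd.DataFrame:
    """Replicate-averaged fold change later/reference per guide.

    fc_t = (mean over replicates at t + pseudocount) /
           (mean at reference + pseudocount). Returns a DataFrame with
    guide_id, gene_id (when a library is supplied) and one fc_<timepoint>
    column per non-reference timepoint.
    """
    cfg = cfg or ScreenConfig()
    timepoints = list(dict.fromkeys(cm.samples["timepoint"]))
    if cfg.reference_timepoint not in timepoints:
        raise ValueError(f"missing reference timepoint {cfg.reference_timepoint!r}")
    means = {}
    for tp in timepoints:
        samples = cm.samples_at(tp)
        if len(samples) < 2:
            log.warning("timepoint %s has a single replicate", tp)
        means[tp] = cm.counts[samples].mean(axis=1)
    ref = means[cfg.reference_timepoint] + cfg.pseudocount
    out = pd.DataFrame({"guide_id": cm.counts.index})
    if library is not None:
        gene_of = dict(zip(library["guide_id"], library["gene_id"]))
        out["gene_id"] = out["guide_id"].map(gene_of)
        if out["gene_id"].isna().any():
            missing = out.loc[out["gene_id"].isna(), "guide_id"].tolist()[:5]
            raise ValueError(f"guides absent from library table: {missing}")
    for tp in timepoints:
        if tp == cfg.reference_timepoint:
            continue
        out[f"fc_{tp}"] = ((means[tp] + cfg.pseudocount) / ref).to_numpy()
    return out


def call_hits(fcs: pd.DataFrame, cfg: ScreenConfig | None = None) -> pd.DataFrame:
    """Gene-level hit table under the fold-depletion rule.

    A guide is depleted when fc at the hit timepoint is <= 1/threshold
    (boundary inclusive); a gene is a hit when at least
    ``min_depleted_guides`` of its guides are depleted. Sorted by the
    gene's minimum fold change, most depleted first.
    """
    cfg = cfg or ScreenConfig()
    col = f"fc_{cfg.hit_timepoint}"
    if col not in fcs.columns:
        raise ValueError(f"missing column {col!r}")
    if "gene_id" not in fcs.columns:
        raise ValueError("fold-change table lacks gene_id")
    cutoff = 1.0 / cfg.hit_fold_threshold
    df = fcs.assign(depleted=fcs[col] <= cutoff)
    table = (df.groupby("gene_id")
               .agg(min_fc=(col, "min"), n_guides_depleted=("depleted", "sum"),
                    n_guides=("guide_id", "count"))
               .reset_index())
    table[f"min_{col}"] = table.pop("min_fc")
    table["is_hit"] = table["n_guides_depleted"] >= cfg.min_depleted_guides
    return table.sort_values(f"min_{col}", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Gene-set comparison and dependency classification

def compare_gene_sets(hits: set, references: Mapping[str, set]) -> dict:
    """Pairwise overlaps and full Venn-region cardinalities for the hit set
    against named reference sets (case-sensitive identifiers)."""
    sets = {"hits": set(hits), **{k: set(v) for k, v in references.items()}}
    names = list(sets)
    pairwise = {}
    for a, b in combinations(names, 2):
        inter = sets[a] & sets[b]
        pairwise[f"{a}&{b}"] = {
            "overlap": len(inter),
            "unique_left": len(sets[a] - sets[b]),
            "unique_right": len(sets[b] - sets[a]),
        }
    universe = set().union(*sets.values()) if sets else set()
    regions = {}
    for gene in universe:
        key = tuple(sorted(n for n in names if gene in sets[n]))
        regions[key] = regions.get(key, 0) + 1
    return {
        "sizes": {n: len(s) for n, s in sets.items()},
        "pairwise": pairwise,
        "venn_regions": {"&".join(k): v for k, v in sorted(regions.items())},
        "union": len(universe),
        "common_to_all": len(set.intersection(*sets.values())) if sets else 0,
    }


def classify_dependency(gene_scores: Mapping[str, Sequence[float]],
                        threshold: float = -0.5) -> pd.DataFrame:
    """Median dependency score per gene; common essential iff the median is
    strictly below the threshold. Ranked most-depleted first."""
    rows = []
    for gene, scores in gene_scores.items():
        if len(scores) == 0:
            raise ValueError(f"gene {gene!r} has no scores")
        med = float(np.median(scores))
        rows.append((gene, med, med < threshold))
    df = pd.DataFrame(rows, columns=["gene_id", "median_score", "common_essential"])
    return df.sort_values("median_score", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Auxiliary rule-based filters

@dataclass(frozen=True)
class PeakRecord:
    chrom: str
    start: int
    end: int
    wt_read_count: int
    fc_wt: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("start >= end")
        if self.wt_read_count < 0:
            raise ValueError("negative read count")


def filter_high_confidence_peaks(peaks: Sequence[PeakRecord],
                                 min_reads: int = 100, max_reads: int = 5000,
                                 min_fc: float = 1.0) -> list[PeakRecord]:
    """Keep peaks with min_reads <= wild-type reads <= max_reads and
    wild-type fold enrichment strictly above min_fc. Idempotent."""
    return [p for p in peaks
            if min_reads <= p.wt_read_count <= max_reads and p.fc_wt > min_fc]


def normalize_competition(gfp: pd.DataFrame, neg_control: pd.Series) -> pd.DataFrame:
    """Normalize GFP+ percentages to day 0 and to the negative control.

    value(s, t) = (gfp(s, t) / gfp(s, 0)) / (neg(t) / neg(0)); every series
    is 1 at day 0 by construction. ``gfp`` is series x day (day 0 must be
    the first column or labelled 0), ``neg_control`` is indexed by day.
    """
    day0 = gfp.columns[0] if 0 not in gfp.columns else 0
    if (gfp[day0] == 0).any() or neg_control[day0] == 0:
        raise ValueError("day-0 percentage of zero")
    rel = gfp.div(gfp[day0], axis=0)
    neg_rel = neg_control / neg_control[day0]
    return rel.div(neg_rel, axis=1)


# ---------------------------------------------------------------------------
# Convenience pipeline

def effective_pseudocount_config(cm_raw: CountMatrix,
                                 cfg: ScreenConfig) -> ScreenConfig:
    """Rescale the read-unit pseudocount onto the mean-normalized scale.

    ``ScreenConfig.pseudocount`` is expressed in reads (default 0.5 reads,
    the usual zero-count guard). Mean normalization maps every sample onto
    a mean of 1, so the equivalent additive constant there is
    pseudocount / (mean raw count of the reference samples).
    """
    from dataclasses import replace

    ref = cm_raw.samples_at(cfg.reference_timepoint)
    if not ref:
        raise ValueError(f"no samples at reference timepoint "
                         f"{cfg.reference_timepoint!r}")
    mean_depth = float(cm_raw.counts[ref].to_numpy().mean())
    if mean_depth <= 0:
        raise ValueError("reference samples have zero mean count")
    return replace(cfg, pseudocount=cfg.pseudocount / mean_depth)


def run_screen_pipeline(cm: CountMatrix, library: pd.DataFrame,
                        cfg: ScreenConfig | None = None) -> dict:
    """normalize -> low-abundance filter -> replicate-averaged fold changes
    -> gene-level hit calling, with non-targeting guides tracked separately
    as the null control."""
    cfg = effective_pseudocount_config(cm, cfg or ScreenConfig())
    normalized = normalize_counts(cm)
    filtered, removed = filter_low_abundance(normalized, cfg)
    fcs = compute_fold_changes(filtered, library, cfg)
    role_of = dict(zip(library["guide_id"], library["role"]))
    fcs["role"] = fcs["guide_id"].map(role_of)
    targeting = fcs[fcs["role"] == "targeting"]
    hits = call_hits(targeting, cfg)
    nt = fcs.loc[fcs["role"] == "non_targeting", f"fc_{cfg.hit_timepoint}"]
    return {
        "normalized": normalized,
        "removed_guides": removed,
        "fold_changes": fcs,
        "hits": hits,
        "nontargeting_median_fc": float(nt.median()) if len(nt) else float("nan"),
    }
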