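"""Synthetic references and simulated dropout screens with known ground truth.

Two generators make the whole pipeline exercisable offline:

* :func:`generate_toy_reference` writes a small genome (FASTA), transcript
  annotation (GTF), domain intervals (BED6) and a domain-category map that
  the library-design stage consumes. Genes are non-overlapping, every
  domain lies inside its gene's single-exon transcript, base composition is
  ~50% GC, and each domain is guaranteed at least ``guides_per_gene`` NGG
  PAM sites (domains are redrawn until the guarantee holds).

* :func:`simulate_screen` draws guide x sample counts for a dropout screen.
  Guide abundance starts log-normal (pooled libraries are strongly skewed),
  essential genes decay geometrically per population doubling — a gene
  planted at D-fold depletion with per-guide efficacy e has expected count
  ratio D^(-e) after 15 doublings — and observed counts are
  negative-binomial around the depth-scaled expectation with dispersion
  alpha (variance mu + alpha*mu^2). Non-targeting and non-essential guides
  keep fitness 1. Everything is reproducible from the mandatory seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (BedRecord, CountMatrix, GtfFeature, atomic_write,
                 write_bed6, write_fasta)
from .library_design import CATEGORIES

# Timepoint labels and the population doublings they correspond to: the
# screen samples at ~10 and ~15 doublings (days 7 and 11; day 1 reference).
TIMEPOINT_DOUBLINGS = {"day1": 0.0, "day7": 10.0, "day11": 15.0}


@dataclass
class SimulationSpec:
    """Study conditions for the toy reference and the simulated screen."""

    n_genes: int = 200
    domains_per_gene: int = 2
    # matches the real library's category composition (catalytic-heavy)
    category_probs: tuple[float, ...] = (0.35, 0.15, 0.27, 0.13, 0.10)
    guides_per_gene: int = 10
    fraction_non_targeting: float = 0.10
    n_positive_controls: int = 20
    baseline_mu: float = 0.0        # log-normal log-mean of guide abundance
    baseline_sigma: float = 1.0     # log-normal log-sd
    dispersion: float = 0.1         # NB alpha; var = mu + alpha mu^2
    depletion_fold: float = 16.0    # planted effect at full efficacy, 15 doublings
    efficacy_beta: tuple[float, float] = (5.0, 1.0)
    replicates: int = 2
    depth_per_guide: float = 300.0  # mean reads per guide per sample
    domain_length: int = 150
    gene_spacing: int = 100

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if abs(sum(self.category_probs) - 1.0) > 1e-9 or \
                any(not 0 <= p <= 1 for p in self.category_probs):
            raise ValueError("category_probs must be probabilities summing to 1")
        if not 0 <= self.fraction_non_targeting < 1:
            raise ValueError("fraction_non_targeting must be in [0, 1)")
        if self.depth_per_guide <= 0:
            raise ValueError("depth must be positive")
        if self.domain_length < 30:
            raise ValueError("domain too short to host guides")


@dataclass
class TruthManifest:
    """Planted ground truth of a simulated screen."""

    essential: dict  # gene_id -> planted fold depletion
    efficacy: dict   # guide_id -> per-guide efficacy in [0, 1]
    non_targeting: list  # guide_ids expected to stay flat

    def to_json(self, path) -> None:
        with atomic_write(path) as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class ToyReference:
    genome: dict
    gtf_features: list
    domains: list
    category_map: dict

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gtf": outdir / "transcripts.gtf",
            "domains": outdir / "domains.bed",
            "categories": outdir / "categories.tsv",
        }
        write_fasta(self.genome, paths["fasta"])
        with atomic_write(paths["gtf"]) as fh:
            for f in self.gtf_features:
                attrs = f'gene_id "{f.gene_id}"; transcript_id "{f.transcript_id}";'
                fh.write(f"{f.chrom}\t{f.source}\t{f.feature}\t{f.start + 1}\t"
                         f"{f.end}\t.\t{f.strand}\t.\t{attrs}\n")
        write_bed6(self.domains, paths["domains"])
        with atomic_write(paths["categories"]) as fh:
            fh.write("domain_name\tcategory\n")
            for name, cat in self.category_map.items():
                fh.write(f"{name}\t{cat}\n")
        return paths


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _count_pam_sites(seq: str) -> int:
    """NGG PAM windows whose full 23-mer lies inside seq, both strands."""
    n = 0
    for s in range(len(seq) - 22):
        if seq[s + 21:s + 23] == "GG":
            n += 1
    for t in range(3, len(seq) - 19):
        if seq[t - 3:t - 1] == "CC":
            n += 1
    return n


def generate_toy_reference(spec: SimulationSpec, seed: int,
                           outdir=None) -> ToyReference:
    """Deterministic toy genome + annotation satisfying the PAM guarantee."""
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    pieces: list[str] = []
    pos = 0
    gtf: list[GtfFeature] = []
    domains: list[BedRecord] = []
    category_map: dict[str, str] = {}
    cats = np.array(CATEGORIES)

    for g in range(spec.n_genes):
        gene_id = f"gene{g + 1:04d}"
        pieces.append(_random_seq(rng, spec.gene_spacing))
        pos += spec.gene_spacing
        gene_start = pos
        domain_parts: list[str] = []
        for d in range(spec.domains_per_gene):
            name = f"{gene_id}_dom{d + 1}"
            for _attempt in range(200):
                seq = _random_seq(rng, spec.domain_length)
                if _count_pam_sites(seq) >= spec.guides_per_gene:
                    break
            else:
                raise ValueError(
                    f"could not place {spec.guides_per_gene} PAM sites in a "
                    f"{spec.domain_length}-nt domain")
            linker = _random_seq(rng, 40)
            dom_start = pos + len(linker)
            domain_parts.extend([linker, seq])
            pos = dom_start + spec.domain_length
            domains.append(BedRecord(chrom, dom_start, pos, name, "0", "+"))
            category_map[name] = str(rng.choice(cats, p=spec.category_probs))
        domain_parts.append(_random_seq(rng, 40))
        pos += 40
        pieces.extend(domain_parts)
        tx_id = f"{gene_id}.t1"
        gtf.append(GtfFeature(chrom, "toy", "transcript", gene_start, pos,
                              "+", gene_id, tx_id))
        gtf.append(GtfFeature(chrom, "toy", "exon", gene_start, pos,
                              "+", gene_id, tx_id))
    pieces.append(_random_seq(rng, spec.gene_spacing))
    ref = ToyReference({chrom: "".join(pieces)}, gtf, domains, category_map)
    if outdir is not None:
        ref.write(outdir)
    return ref


# ---------------------------------------------------------------------------
# Screen simulation

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 1e-9:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_screen(library: pd.DataFrame, truth: dict,
                    spec: SimulationSpec, seed: int
                    ) -> tuple[CountMatrix, TruthManifest]:
    """Simulate guide counts for every timepoint/replicate of the screen.

    ``truth`` maps gene_id -> planted fold depletion (at full efficacy over
    15 doublings); genes absent from it are neutral. Per-guide efficacies
    are drawn Beta(*spec.efficacy_beta*) for guides of planted genes.
    """
    if len(library) == 0:
        raise ValueError("empty library")
    rng = np.random.default_rng(seed)
    guides = library["guide_id"].to_numpy()
    genes = library["gene_id"].to_numpy()
    roles = library["role"].to_numpy()

    baseline = rng.lognormal(spec.baseline_mu, spec.baseline_sigma, size=len(guides))
    efficacy = np.zeros(len(guides))
    fitness = np.ones(len(guides))
    a, b = spec.efficacy_beta
    for i, (gene, role) in enumerate(zip(genes, roles)):
        fold = truth.get(gene)
        if fold is not None and role != "non_targeting":
            efficacy[i] = rng.beta(a, b)
            # fold-depletion at 15 doublings scaled by efficacy
            fitness[i] = fold ** (-efficacy[i] / 15.0)

    samples = []
    columns = {}
    for tp, doublings in TIMEPOINT_DOUBLINGS.items():
        rel = baseline * fitness ** doublings
        mu = rel / rel.mean() * spec.depth_per_guide
        for rep in range(1, spec.replicates + 1):
            sid = f"{tp}_r{rep}"
            samples.append((sid, tp, rep))
            columns[sid] = _nb_draw(rng, mu, spec.dispersion)

    counts = pd.DataFrame(columns, index=pd.Index(guides, name="guide_id"))
    sheet = (pd.DataFrame(samples, columns=["sample_id", "timepoint", "replicate"])
             .set_index("sample_id"))
    manifest = TruthManifest(
        essential={g: float(f) for g, f in truth.items()},
        efficacy={gid: float(e) for gid, e in zip(guides, efficacy)},
        non_targeting=[gid for gid, r in zip(guides, roles)
                       if r == "non_targeting"],
    )
    return CountMatrix(counts, sheet), manifest


def simulated_library(spec: SimulationSpec, seed: int) -> pd.DataFrame:
    """A library table for count simulation only (no genomic design run):
    random distinct protospacers with the spec's gene/guide/control layout."""
    rng = np.random.default_rng(seed)
    seen: set[str] = set()

    def draw() -> str:
        while True:
            ps = "G" + _random_seq(rng, 19)
            if ps not in seen:
                seen.add(ps)
                return ps

    rows = []
    for g in range(spec.n_genes):
        gene = f"gene{g + 1:04d}"
        for i in range(1, spec.guides_per_gene + 1):
            rows.append((f"{gene}_g{i:02d}", gene, f"{gene}_dom1", "catalytic",
                         "targeting", draw()))
    for p in range(spec.n_positive_controls):
        gene = f"posctrl{p + 1:02d}"
        for i in range(1, spec.guides_per_gene + 1):
            rows.append((f"{gene}_pc_{i:02d}", gene, "positive_control", "other",
                         "positive_control", draw()))
    n_total_targeting = len(rows)
    n_nt = round(n_total_targeting * spec.fraction_non_targeting
                 / (1 - spec.fraction_non_targeting))
    for i in range(1, n_nt + 1):
        rows.append((f"NT_{i:04d}", "non-targeting", "non_targeting", "other",
                     "non_targeting", draw()))
    df = pd.DataFrame(rows, columns=["guide_id", "gene_id", "domain_name",
                                     "category", "role", "protospacer"])
    df["oligo"] = "TGTATGAGACGCGTATGCTG" + df["protospacer"] + \
        "GTTTCGTCTCACTGGAGCAC"
    return df
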