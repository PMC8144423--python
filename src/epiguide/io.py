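"""Readers and writers for the file formats the pipeline touches.

Coordinates are 0-based half-open everywhere inside the package. BED is
native in that convention; GTF is 1-based inclusive and converted on read.
GTF is only ever read, never written by analysis code (the synthetic-data
generator emits it for round-trip testing).

All writers go through :func:`atomic_write`: output is written to a
temporary file in the destination directory and renamed into place, so a
failure never leaves a partial output file behind.
"""

from __future__ import annotations

import contextlib
import json
import logging
import os
import re
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

log = logging.getLogger("epiguide")

LIBRARY_COLUMNS = [
    "guide_id",
    "gene_id",
    "domain_name",
    "category",
    "role",
    "protospacer",
    "oligo",
]
ROLES = ("targeting", "non_targeting", "positive_control")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@contextlib.contextmanager
def atomic_write(path: str | os.PathLike, mode: str = "w") -> Iterator:
    """Write to a temp file and rename into place on success."""
    path = os.fspath(path)
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix=os.path.basename(path))
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        with contextlib.suppress(OSError):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"duplicate sequence name {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with atomic_write(path) as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# BED6 / GTF

@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    name: str
    score: str = "0"
    strand: str = "+"


@dataclass(frozen=True)
class GtfFeature:
    chrom: str
    source: str
    feature: str
    start: int  # converted to 0-based
    end: int    # half-open
    strand: str
    gene_id: str
    transcript_id: str


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_bed6(path) -> list[BedRecord]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{i}: expected 6 BED columns, got {len(parts)}")
            chrom, start, end, name, score, strand = parts[:6]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer coordinate") from exc
            if e <= s:
                raise ParseError(f"{path}:{i}: end <= start ({s}, {e})")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{i}: bad strand {strand!r}")
            out.append(BedRecord(chrom, s, e, name, score, strand))
    return out


def write_bed6(records: Iterable[BedRecord], path) -> None:
    with atomic_write(path) as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t{r.strand}\n")


def read_gtf(path) -> list[GtfFeature]:
    """Minimal GTF reader (transcript/exon/gene features, quoted attributes).

    1-based inclusive coordinates are converted to 0-based half-open.
    """
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{i}: expected 9 GTF columns, got {len(parts)}")
            chrom, source, feature, start, end, _score, strand, _frame, attrs = parts
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer coordinate") from exc
            if e <= s:
                raise ParseError(f"{path}:{i}: end <= start after conversion")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{i}: bad strand {strand!r}")
            a = dict(_ATTR_RE.findall(attrs))
            out.append(
                GtfFeature(
                    chrom, source, feature, s, e, strand,
                    a.get("gene_id", ""), a.get("transcript_id", ""),
                )
            )
    return out


def read_regions(path, dialect: str | None = None):
    """Read intervals from BED6 or GTF; dialect inferred from extension."""
    if dialect is None:
        ext = os.path.splitext(os.fspath(path))[1].lower()
        dialect = {".bed": "bed6", ".bed6": "bed6", ".gtf": "gtf"}.get(ext)
        if dialect is None:
            raise ParseError(f"cannot infer dialect from extension of {path}")
    if dialect.lower() == "bed6":
        return read_bed6(path)
    if dialect.lower() == "gtf":
        return read_gtf(path)
    raise ParseError(f"unknown dialect {dialect!r}")


class TranscriptSet:
    """Transcript/exon intervals indexed for fast overlap queries.

    Built from GTF features; exon features define exons, transcript span is
    the transcript feature when present else the envelope of its exons.
    """

    def __init__(self, features: Iterable[GtfFeature]):
        self.transcripts: dict[str, dict] = {}
        exon_bins: dict[str, list[tuple[int, int]]] = {}
        for f in features:
            if not f.transcript_id:
                continue
            t = self.transcripts.setdefault(
                f.transcript_id,
                {"chrom": f.chrom, "strand": f.strand, "gene_id": f.gene_id,
                 "start": None, "end": None, "exons": []},
            )
            if f.feature == "transcript":
                t["start"], t["end"] = f.start, f.end
            elif f.feature == "exon":
                t["exons"].append((f.start, f.end))
                exon_bins.setdefault(f.chrom, []).append((f.start, f.end))
        self._exon_trees: dict[str, IntervalTree] = {}
        self._tx_trees: dict[str, IntervalTree] = {}
        for tid, t in self.transcripts.items():
            if t["start"] is None:
                if not t["exons"]:
                    continue
                t["start"] = min(s for s, _ in t["exons"])
                t["end"] = max(e for _, e in t["exons"])
            self._tx_trees.setdefault(t["chrom"], IntervalTree()).addi(
                t["start"], t["end"], tid
            )
            for s, e in t["exons"]:
                self._exon_trees.setdefault(t["chrom"], IntervalTree()).addi(s, e, tid)

    def overlapping_transcripts(self, chrom: str, start: int, end: int) -> list[str]:
        tree = self._tx_trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end)})

    def overlaps_exon(self, chrom: str, start: int, end: int) -> bool:
        tree = self._exon_trees.get(chrom)
        return tree is not None and bool(tree.overlap(start, end))

    def gene_of(self, transcript_id: str) -> str:
        return self.transcripts[transcript_id]["gene_id"]


def read_category_map(path) -> dict[str, str]:
    """TSV of (domain_name, category); header optional."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{i}: expected 2 columns")
            if i == 1 and parts[0].lower() in ("domain_name", "domain"):
                continue
            out[parts[0]] = parts[1]
    return out


# ---------------------------------------------------------------------------
# Library table

def validate_library_table(df: pd.DataFrame, origin: str = "<table>") -> pd.DataFrame:
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{origin}: missing library columns {missing}")
    dup = df["guide_id"][df["guide_id"].duplicated(keep=False)]
    if len(dup):
        lines = [f"{gid} (rows {', '.join(str(i + 2) for i in idx)})"
                 for gid, idx in dup.groupby(dup).groups.items()]
        raise ParseError(f"{origin}: duplicate guide_id: " + "; ".join(lines))
    bad_role = df.loc[~df["role"].isin(ROLES), "role"]
    if len(bad_role):
        raise ParseError(f"{origin}: invalid role values {sorted(set(bad_role))}")
    bad_ps = df.index[df["protospacer"].str.len() != 20]
    if len(bad_ps):
        rows = ", ".join(str(i + 2) for i in bad_ps[:10])
        raise ParseError(f"{origin}: protospacer not 20 nt at rows {rows}")
    return df


def read_library_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    validate_library_table(df, origin=os.fspath(path))
    counts = df["role"].value_counts().to_dict()
    log.info("library %s: %d guides (%s)", path, len(df),
             ", ".join(f"{k}={v}" for k, v in sorted(counts.items())))
    return df


def write_library_table(df: pd.DataFrame, path) -> None:
    validate_library_table(df)
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count tables

@dataclass
class CountMatrix:
    """Guide x sample counts plus per-sample metadata.

    counts: DataFrame indexed by guide_id, one column per sample_id.
    samples: DataFrame indexed by sample_id with columns timepoint, replicate.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        unknown = [s for s in self.counts.columns if s not in self.samples.index]
        if unknown:
            raise ParseError(f"samples in counts but not in sample sheet: {unknown}")
        if (self.counts.to_numpy() < 0).any():
            bad = self.counts.stack()
            bad = bad[bad < 0]
            g, s = bad.index[0]
            raise ParseError(f"negative count at guide {g!r}, sample {s!r}")

    def samples_at(self, timepoint: str) -> list[str]:
        return list(self.samples.index[self.samples["timepoint"] == timepoint])


def read_count_table(counts_path, sheet_path) -> CountMatrix:
    sheet = pd.read_csv(sheet_path, sep="\t", dtype={"sample_id": str, "timepoint": str})
    for col in ("sample_id", "timepoint", "replicate"):
        if col not in sheet.columns:
            raise ParseError(f"{sheet_path}: missing column {col!r}")
    sheet = sheet.set_index("sample_id")
    raw = pd.read_csv(counts_path, sep="\t", dtype=str).set_index("guide_id")
    mat = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        try:
            mat[col] = raw[col].astype(int)
        except ValueError:
            bad = raw.index[pd.to_numeric(raw[col], errors="coerce").isna()][0]
            raise ParseError(
                f"{counts_path}: non-integer count at guide {bad!r}, sample {col!r}"
            ) from None
    return CountMatrix(mat, sheet)


def write_count_table(cm: CountMatrix, counts_path, sheet_path) -> None:
    with atomic_write(counts_path) as fh:
        cm.counts.rename_axis("guide_id").to_csv(fh, sep="\t")
    with atomic_write(sheet_path) as fh:
        cm.samples.rename_axis("sample_id").to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Peaks / hits / generic TSV

def read_peaks(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "start", "end", "wt_read_count", "fc_wt"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing peak column {col!r}")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index=index)


# ---------------------------------------------------------------------------
# Config / manifests

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with atomic_write(path) as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_json(obj, path) -> None:
    with atomic_write(path) as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
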