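"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written by the most direct route available
(exhaustive window scans, quadratic tie-averaged ranking) and shares no
code with the package paths it verifies.
"""

from __future__ import annotations

import numpy as np

COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def brute_force_hits(genome: dict[str, str], guide23: str,
                     max_mm: int = 3) -> set[tuple[str, int, str, int]]:
    """Every (chrom, start, strand, n_mismatches) with Hamming <= max_mm,
    via an exhaustive sliding-window scan of both strands."""
    out = set()
    q_fwd = np.frombuffer(guide23.encode(), dtype=np.uint8)
    q_rev = np.frombuffer(rc(guide23).encode(), dtype=np.uint8)
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(arr) < 23:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, 23)
        for strand, q in (("+", q_fwd), ("-", q_rev)):
            mism = (windows != q).sum(axis=1)
            for start in np.nonzero(mism <= max_mm)[0]:
                out.add((chrom, int(start), strand, int(mism[start])))
    return out


def brute_force_candidates(chrom_seq: str, a: int, b: int,
                           min_run: int = 8, require_g: bool = True
                           ) -> set[tuple[int, str, str]]:
    """Exhaustive NGG window scan of both strands of [a, b); returns
    (protospacer start on plus strand, strand, protospacer)."""
    runs: list[tuple[int, int]] = []
    i = a
    while i < b:
        j = i + 1
        while j < b and chrom_seq[j] == chrom_seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j))
        i = j

    def low(s: int, e: int) -> bool:
        return any(s < re_ and rs < e for rs, re_ in runs)

    out = set()
    n = len(chrom_seq)
    for s in range(a, b):
        # plus: protospacer [s, s+20), PAM [s+20, s+23)
        if s + 23 <= b and chrom_seq[s + 21:s + 23] == "GG":
            if s - 4 >= 0 and s + 26 <= n:
                ctx = chrom_seq[s - 4:s + 26]
                ps = ctx[4:24]
                if "N" not in ctx and not low(s, s + 20) and \
                        (not require_g or ps.startswith("G")):
                    out.add((s, "+", ps))
        # minus: plus-strand CC at [t-3, t-1), protospacer revcomp of [t, t+20)
        t = s
        if t - 3 >= a and t + 20 <= b and chrom_seq[t - 3:t - 1] == "CC":
            if t - 6 >= 0 and t + 24 <= n:
                ctx = rc(chrom_seq[t - 6:t + 24])
                ps = ctx[4:24]
                if "N" not in ctx and not low(t, t + 20) and \
                        (not require_g or ps.startswith("G")):
                    out.add((t, "-", ps))
    return out


def tie_average_ranks(values, descending: bool = False) -> list[float]:
    """Rank with average ties, computed by counting, not sorting libraries."""
    ranks = []
    for v in values:
        smaller = sum(1 for w in values if (w > v if descending else w < v))
        equal = sum(1 for w in values if w == v)
        ranks.append(smaller + (equal + 1) / 2)
    return ranks


def brute_force_rank_scores(criteria_rows: list[tuple]) -> list[float]:
    """Mean of seven component ranks: column 0 descending, rest ascending."""
    cols = list(zip(*criteria_rows))
    per_col = [tie_average_ranks(cols[0], descending=True)]
    per_col += [tie_average_ranks(c) for c in cols[1:]]
    return [sum(col[i] for col in per_col) / len(per_col)
            for i in range(len(criteria_rows))]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
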