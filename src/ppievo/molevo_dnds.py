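"""Pairwise dN/dS estimation by Nei-Gojobori (1986) counting.

Implements the classic codon-counting estimator of the ratio of
nonsynonymous to synonymous substitution rates (omega = dN/dS) for a
pair of in-frame aligned coding sequences:

* every codon position contributes synonymous/nonsynonymous *site*
  fractions according to which of its three possible single-nucleotide
  changes preserve the encoded amino acid (changes to stop codons are
  excluded, with renormalization so each codon contributes exactly
  three sites);
* observed codon *differences* are classified by averaging the
  synonymous/nonsynonymous step counts over all substitution pathways
  (orderings of the mismatched positions), skipping pathways that pass
  through a stop codon;
* the proportions pS = Sd/S and pN = Nd/N are corrected for multiple
  hits with the Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3).

omega > 1 indicates positive selection, omega << 1 purifying selection.
Codon columns containing gaps, ambiguity codes, or stop codons in either
sequence are removed before counting (complete deletion).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import pandas as pd
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

__all__ = [
    "CodonAlignment",
    "DnDsEstimate",
    "codon_sites",
    "codon_differences",
    "dnds_pairwise",
    "batch_dnds",
    "write_phylip",
]

BASES = "ACGT"


@lru_cache(maxsize=None)
def _code(table_id: int = 1) -> dict[str, str]:
    """Codon -> amino acid map ('*' for stop) for an NCBI translation table."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


def _check_sense(codon: str, code: dict[str, str]) -> None:
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if code[codon] == "*":
        raise ValueError(f"stop codon: {codon!r}")


@lru_cache(maxsize=None)
def codon_sites(codon: str, table_id: int = 1) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) of one sense codon.

    At each of the three positions the fraction of the single-nucleotide
    changes that are synonymous is taken over non-stop changes only; the
    two fractions are renormalized so s + n = 3 for every codon.
    """
    code = _code(table_id)
    _check_sense(codon, code)
    aa = code[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if code[mutant] == "*":
                continue
            non_stop += 1
            if code[mutant] == aa:
                syn += 1
        if non_stop:
            s += syn / non_stop
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_differences(
    codon1: str, codon2: str, table_id: int = 1
) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) step counts between two codons.

    For k mismatched positions all k! substitution orderings are
    enumerated; pathways passing through a stop codon are skipped and the
    step counts averaged over the remaining pathways, so sd + nd equals
    the number of mismatches whenever a stop-free pathway exists. If every
    pathway passes through a stop, the average is taken over all pathways
    (documented fallback).
    """
    code = _code(table_id)
    _check_sense(codon1, code)
    _check_sense(codon2, code)
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        sd = nd = 0
        current = codon1
        for pos in order:
            nxt = current[:pos] + codon2[pos] + current[pos + 1 :]
            if code[nxt] == "*":
                return None
            if code[nxt] == code[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        return sd, nd

    valid: list[tuple[float, float]] = []
    through_stop: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        result = walk(order)
        if result is not None:
            valid.append(result)
        else:
            # fallback accounting: classify every step, stops included
            sd = nd = 0
            current = codon1
            for pos in order:
                nxt = current[:pos] + codon2[pos] + current[pos + 1 :]
                if code[nxt] == code[current]:
                    sd += 1
                else:
                    nd += 1
                current = nxt
            through_stop.append((sd, nd))
    paths = valid if valid else through_stop
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


@dataclass
class CodonAlignment:
    """Filtered pairwise in-frame codon alignment.

    ``codons1``/``codons2`` hold the retained codon columns; columns with
    gaps, ambiguity characters or stop codons in either sequence were
    dropped (complete deletion) and counted in ``n_dropped``.
    """

    codons1: list[str]
    codons2: list[str]
    table_id: int = 1
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if len(self.codons1) != len(self.codons2):
            raise ValueError("codon lists differ in length")

    @property
    def n_codons(self) -> int:
        return len(self.codons1)

    @classmethod
    def from_sequences(
        cls, seq1: str, seq2: str, table_id: int = 1
    ) -> "CodonAlignment":
        seq1, seq2 = seq1.upper(), seq2.upper()
        if len(seq1) != len(seq2):
            raise ValueError(
                f"aligned sequences differ in length: {len(seq1)} vs {len(seq2)}"
            )
        if len(seq1) % 3:
            raise ValueError(f"alignment length {len(seq1)} not divisible by 3")
        code = _code(table_id)
        c1, c2, dropped = [], [], 0
        for i in range(0, len(seq1), 3):
            a, b = seq1[i : i + 3], seq2[i : i + 3]
            clean = all(ch in BASES for ch in a + b)
            if clean and code[a] != "*" and code[b] != "*":
                c1.append(a)
                c2.append(b)
            else:
                dropped += 1
        return cls(c1, c2, table_id=table_id, n_dropped=dropped)


@dataclass
class DnDsEstimate:
    """NG86 counts and Jukes-Cantor-corrected distances for one pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float  # NaN when saturated (p >= 3/4)
    dN: float
    omega: float  # NaN when undefined (dS == 0 or saturation)
    n_codons: int
    status: str = "ok"


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def dnds_pairwise(aln: CodonAlignment) -> DnDsEstimate:
    """NG86 pairwise dN/dS over the comparable codon columns of ``aln``.

    Site counts are averaged over the two sequences; omega is flagged
    undefined (NaN, status) when dS = 0 or either proportion is
    saturated (p >= 3/4, where the Jukes-Cantor correction diverges).
    """
    if aln.n_codons == 0:
        raise ValueError("no comparable codon columns")
    S = N = Sd = Nd = 0.0
    for c1, c2 in zip(aln.codons1, aln.codons2):
        s1, n1 = codon_sites(c1, aln.table_id)
        s2, n2 = codon_sites(c2, aln.table_id)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = codon_differences(c1, c2, aln.table_id)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    status = "ok"
    if math.isnan(dS) or math.isnan(dN):
        omega = math.nan
        status = "saturated"
    elif dS == 0.0:
        omega = math.nan
        status = "dS_zero"
    else:
        omega = dN / dS
    return DnDsEstimate(S, N, Sd, Nd, pS, pN, dS, dN, omega, aln.n_codons, status)


def batch_dnds(manifest: pd.DataFrame, loader=None) -> pd.DataFrame:
    """dN/dS for a batch of pairwise alignment files.

    ``manifest`` needs columns ``gene``, ``file``, ``species_a``,
    ``species_b``. Per-gene failures (unreadable or out-of-frame files)
    are recorded in the ``status`` column rather than raised.
    """
    if loader is None:
        from .io_cli import read_fasta_pair

        loader = read_fasta_pair
    rows = []
    for rec in manifest.itertuples():
        row = {
            "gene": rec.gene,
            "species_a": rec.species_a,
            "species_b": rec.species_b,
        }
        try:
            aln = loader(rec.file)
            est = dnds_pairwise(aln)
            row.update(
                S=est.S, N=est.N, Sd=est.Sd, Nd=est.Nd, pS=est.pS, pN=est.pN,
                dS=est.dS, dN=est.dN, omega=est.omega, n_codons=est.n_codons,
                status=est.status,
            )
        except Exception as exc:  # per-gene failures are data, not crashes
            logger.warning("dN/dS failed for %s: %s", rec.gene, exc)
            row["status"] = f"failed: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def write_phylip(aln: CodonAlignment, names: tuple[str, str], path) -> None:
    """Export the filtered alignment in sequential PHYLIP format."""
    seqs = ["".join(aln.codons1), "".join(aln.codons2)]
    with open(path, "w") as fh:
        fh.write(f" 2 {len(seqs[0])}\n")
        for name, seq in zip(names, seqs):
            fh.write(f"{name[:10]:<10}{seq}\n")
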