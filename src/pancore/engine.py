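"""All-vs-all protein similarity with E-values.

The built-in engine scores pairs by exact Smith-Waterman local alignment
(BLOSUM62, affine gaps, BLAST convention: a gap of length k costs
open + extend*k) and converts raw scores to E-values with the Karlin-Altschul
formula E = K*m*n*exp(-lambda*S), where m is the query length and n the total
residue count of the subject proteome. Only hit *ranks* matter downstream
(best hits and a threshold), so the standard gapped parameters are fixed and
no edge-effect length correction is applied.

Hit tables are 12-column tab-separated (BLAST outfmt-6 compatible); tables
from external aligners can be ingested with :func:`read_hit_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .io import ProteomeSet

KARLIN_LAMBDA = 0.267
KARLIN_K = 0.041
GAP_OPEN = 11
GAP_EXTEND = 1
DEFAULT_KMER = 6

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

_MATRIX = None
_MATRIX_ALPHABET: set[str] = set()


def _blosum62():
    global _MATRIX, _MATRIX_ALPHABET
    if _MATRIX is None:
        from skbio.sequence import SubstitutionMatrix

        _MATRIX = SubstitutionMatrix.by_name("BLOSUM62")
        _MATRIX_ALPHABET = {str(c) for c in _MATRIX.alphabet}
    return _MATRIX


def substitution_score(a: str, b: str) -> float:
    """BLOSUM62 score for one residue pair."""
    m = _blosum62()
    return float(m[a, b])


def align_pair(query: str, subject: str, gap_open: int = GAP_OPEN,
               gap_extend: int = GAP_EXTEND) -> float:
    """Smith-Waterman local alignment raw score; symmetric in its arguments."""
    from skbio.alignment import pair_align

    if not query or not subject:
        raise ValueError("empty sequence")
    matrix = _blosum62()
    for seq in (query, subject):
        bad = set(seq) - _MATRIX_ALPHABET
        if bad:
            raise ValueError(f"characters outside the alphabet: {sorted(bad)}")
    res = pair_align(query, subject, mode="local", sub_score=matrix,
                     gap_cost=(gap_open, gap_extend), max_paths=0, atol=None)
    return float(res.score)


def evalue_from_score(score: float, query_length: int, database_length: int,
                      K: float = KARLIN_K, lam: float = KARLIN_LAMBDA) -> float:
    """Karlin-Altschul E-value: expected chance matches scoring >= ``score``."""
    if query_length <= 0 or database_length <= 0:
        raise ValueError("sequence/database lengths must be positive")
    if K <= 0 or lam <= 0:
        raise ValueError("K and lambda must be positive")
    return K * query_length * database_length * math.exp(-lam * score)


def bit_score(score: float, K: float = KARLIN_K, lam: float = KARLIN_LAMBDA) -> float:
    return (lam * score - math.log(K)) / math.log(2.0)


@dataclass(frozen=True)
class Hit:
    """One directed similarity hit (query protein -> subject protein)."""

    query_id: str
    subject_id: str
    bitscore: float
    evalue: float


class HitTable:
    """Directed hits for one proteome pair, stored in outfmt-6 columns."""

    def __init__(self, frame: pd.DataFrame | None = None) -> None:
        if frame is None:
            frame = pd.DataFrame(columns=OUTFMT6_COLUMNS)
        missing = [c for c in OUTFMT6_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"hit table missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @staticmethod
    def from_hits(hits: list[Hit]) -> "HitTable":
        rows = [
            (h.query_id, h.subject_id, 0.0, 0, 0, 0, 0, 0, 0, 0, h.evalue, h.bitscore)
            for h in hits
        ]
        return HitTable(pd.DataFrame(rows, columns=OUTFMT6_COLUMNS))

    def best_hits(self) -> dict[str, Hit]:
        """Per-query best hit: minimal E-value, ties broken by larger bit
        score, then lexicographically smallest subject ID. Idempotent."""
        best: dict[str, Hit] = {}
        for q, s, e, b in zip(self.frame["qseqid"], self.frame["sseqid"],
                              self.frame["evalue"], self.frame["bitscore"]):
            cur = best.get(q)
            if cur is None or (e, -b, s) < (cur.evalue, -cur.bitscore, cur.subject_id):
                best[q] = Hit(q, s, float(b), float(e))
        return best

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.frame.itertuples(index=False):
                fh.write(
                    f"{row.qseqid}\t{row.sseqid}\t{row.pident:.2f}\t{row.length}\t"
                    f"{row.mismatch}\t{row.gapopen}\t{row.qstart}\t{row.qend}\t"
                    f"{row.sstart}\t{row.send}\t{row.evalue:.3e}\t{row.bitscore:.1f}\n"
                )


def read_hit_table(path) -> HitTable:
    """Read a 12-column tabular hit file; malformed rows report their line."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"{path}: malformed row at line {lineno} "
                                 f"({len(parts)} columns, expected 12)")
            try:
                rows.append((
                    parts[0], parts[1], float(parts[2]), int(parts[3]),
                    int(parts[4]), int(parts[5]), int(parts[6]), int(parts[7]),
                    int(parts[8]), int(parts[9]), float(parts[10]), float(parts[11]),
                ))
            except ValueError:
                raise ValueError(f"{path}: malformed row at line {lineno}") from None
    return HitTable(pd.DataFrame(rows, columns=OUTFMT6_COLUMNS))


# ---------------------------------------------------------------------------
# All-vs-all
# ---------------------------------------------------------------------------

def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _kmer_index(pids: list[str], sequences: dict[str, str], k: int) -> dict[str, list[str]]:
    index: dict[str, list[str]] = {}
    for pid in pids:
        for kmer in _kmers(sequences[pid], k):
            index.setdefault(kmer, []).append(pid)
    return index


def candidate_pairs(pids_a: list[str], pids_b: list[str], sequences: dict[str, str],
                    k: int = DEFAULT_KMER) -> set[tuple[str, str]]:
    """Protein pairs sharing at least one k-mer (alignment prescreen)."""
    index = _kmer_index(pids_a, sequences, k)
    pairs: set[tuple[str, str]] = set()
    for pid_b in pids_b:
        partners: set[str] = set()
        for kmer in _kmers(sequences[pid_b], k):
            partners.update(index.get(kmer, ()))
        pairs.update((pid_a, pid_b) for pid_a in partners)
    return pairs


def all_vs_all(pset: ProteomeSet, kmer_size: int = DEFAULT_KMER,
               gap_open: int = GAP_OPEN, gap_extend: int = GAP_EXTEND,
               ) -> dict[tuple[str, str], HitTable]:
    """Directed hit tables for every ordered isolate pair.

    Alignment is computed once per unordered protein pair (the score is
    symmetric) and reported in both directions with direction-specific
    E-values. Pairs sharing no ``kmer_size``-mer are skipped. For n_o
    isolates the result holds n_o*(n_o-1) tables; within-isolate comparisons
    are never run (singlet status is defined by absent cross-isolate edges).
    """
    from skbio.alignment import pair_align
    from skbio.sequence import Protein

    labels = pset.labels()
    if len(labels) < 2:
        raise ValueError("all_vs_all needs at least two isolates")
    matrix = _blosum62()
    cache: dict[str, Protein] = {}

    def prot(pid: str) -> Protein:
        if pid not in cache:
            cache[pid] = Protein(pset.sequences[pid])
        return cache[pid]

    residues = {lab: pset.residues_of(lab) for lab in labels}
    tables: dict[tuple[str, str], list[Hit]] = {
        (a, b): [] for a in labels for b in labels if a != b
    }
    for i, lab_a in enumerate(labels):
        for lab_b in labels[i + 1:]:
            pids_a = pset.proteins_of(lab_a)
            pids_b = pset.proteins_of(lab_b)
            for pid_a, pid_b in sorted(candidate_pairs(pids_a, pids_b,
                                                       pset.sequences, kmer_size)):
                res = pair_align(prot(pid_a), prot(pid_b), mode="local",
                                 sub_score=matrix, gap_cost=(gap_open, gap_extend),
                                 max_paths=0, atol=None)
                score = float(res.score)
                if score <= 0:
                    continue
                bits = bit_score(score)
                e_ab = evalue_from_score(score, len(pset.sequences[pid_a]),
                                         residues[lab_b])
                e_ba = evalue_from_score(score, len(pset.sequences[pid_b]),
                                         residues[lab_a])
                tables[(lab_a, lab_b)].append(Hit(pid_a, pid_b, bits, e_ab))
                tables[(lab_b, lab_a)].append(Hit(pid_b, pid_a, bits, e_ba))
    return {pair: HitTable.from_hits(hits) for pair, hits in tables.items()}
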