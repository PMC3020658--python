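"""File formats and in-memory containers.

Proteome FASTA headers follow the convention ``genus|species|isolate|protein``;
the full header is the globally unique protein ID, and the first three fields
form the isolate label. Derived tables are written as plain TSV so they can be
diffed and re-read losslessly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True, order=True)
class Isolate:
    """Identity of a sequenced isolate: genus, species and strain name."""

    genus: str
    species: str
    name: str

    @property
    def label(self) -> str:
        return f"{self.genus}|{self.species}|{self.name}"

    @staticmethod
    def from_label(label: str) -> "Isolate":
        genus, species, name = label.split("|")
        return Isolate(genus, species, name)


def protein_isolate_label(protein_id: str) -> str:
    """Isolate label (``genus|species|isolate``) encoded in a protein ID."""
    parts = protein_id.split("|")
    if len(parts) != 4:
        raise ValueError(
            f"protein ID {protein_id!r} does not follow genus|species|isolate|protein"
        )
    return "|".join(parts[:3])


class ProteomeSet:
    """All proteomes under comparison, indexed by isolate label.

    Holds the universe sizes the E-value threshold formula needs: ``n_o``
    (number of organisms) and ``n_p`` (size of the largest proteome).
    """

    def __init__(self) -> None:
        self.isolates: list[Isolate] = []
        self._by_label: dict[str, Isolate] = {}
        self.sequences: dict[str, str] = {}
        self._proteins: dict[str, list[str]] = {}

    def add_isolate(self, isolate: Isolate) -> None:
        if isolate.label in self._by_label:
            raise ValueError(f"duplicate isolate {isolate.label}")
        self.isolates.append(isolate)
        self._by_label[isolate.label] = isolate
        self._proteins[isolate.label] = []

    def add_protein(self, isolate: Isolate, protein_id: str, sequence: str) -> None:
        if protein_id in self.sequences:
            raise ValueError(f"duplicate protein ID {protein_id}")
        if not sequence:
            raise ValueError(f"empty sequence for {protein_id}")
        if isolate.label not in self._by_label:
            self.add_isolate(isolate)
        self.sequences[protein_id] = sequence
        self._proteins[isolate.label].append(protein_id)

    # -- queries -----------------------------------------------------------

    def proteins_of(self, isolate_label: str) -> list[str]:
        return self._proteins[isolate_label]

    def isolate_of(self, protein_id: str) -> str:
        return protein_isolate_label(protein_id)

    def proteome_size(self, isolate_label: str) -> int:
        return len(self._proteins[isolate_label])

    def residues_of(self, isolate_label: str) -> int:
        return sum(len(self.sequences[p]) for p in self._proteins[isolate_label])

    @property
    def n_o(self) -> int:
        return len(self.isolates)

    @property
    def n_p(self) -> int:
        return max(len(v) for v in self._proteins.values())

    def labels(self) -> list[str]:
        return [iso.label for iso in self.isolates]

    def genera(self) -> dict[str, list[str]]:
        """Mapping genus -> ordered isolate labels."""
        out: dict[str, list[str]] = {}
        for iso in self.isolates:
            out.setdefault(iso.genus, []).append(iso.label)
        return out

    def subset(self, isolate_labels: Iterable[str]) -> "ProteomeSet":
        sub = ProteomeSet()
        for lab in isolate_labels:
            iso = self._by_label[lab]
            sub.add_isolate(iso)
            for pid in self._proteins[lab]:
                sub.sequences[pid] = self.sequences[pid]
                sub._proteins[lab].append(pid)
        return sub

    # -- I/O ---------------------------------------------------------------

    @staticmethod
    def from_fasta_dir(path: str | os.PathLike) -> "ProteomeSet":
        """Load one FASTA file per isolate from a directory (sorted order)."""
        pset = ProteomeSet()
        files = sorted(Path(path).glob("*.fasta")) + sorted(Path(path).glob("*.fa"))
        if not files:
            raise FileNotFoundError(f"no FASTA files under {path}")
        for f in files:
            for pid, seq in read_fasta(f).items():
                iso = Isolate.from_label(protein_isolate_label(pid))
                pset.add_protein(iso, pid, seq)
        return pset

    def write_fasta_dir(self, path: str | os.PathLike) -> list[Path]:
        outdir = Path(path)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for iso in self.isolates:
            fname = outdir / (iso.label.replace("|", "_") + ".fasta")
            write_fasta(
                {pid: self.sequences[pid] for pid in self._proteins[iso.label]}, fname
            )
            written.append(fname)
        return written

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            {
                "isolate": iso.label,
                "genus": iso.genus,
                "species": iso.species,
                "proteome_size": self.proteome_size(iso.label),
            }
            for iso in self.isolates
        ]
        return pd.DataFrame(rows)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Line wrapping is irrelevant; duplicate IDs and empty sequences are errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate ID {rec.id} in {path}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for {rec.id} in {path}")
        records[rec.id] = seq
    return records


def write_fasta(records: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    recs = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def write_report(frame: pd.DataFrame, path: str | os.PathLike, columns: list[str] | None = None,
                 float_format: str = "%.4f") -> None:
    """Write a derived table as TSV with a fixed column order.

    ``columns`` pins the schema; a mismatch with the frame is an error.
    """
    if columns is not None:
        missing = [c for c in columns if c not in frame.columns]
        if missing:
            raise ValueError(f"schema mismatch, missing columns: {missing}")
        frame = frame[columns]
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_report(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
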