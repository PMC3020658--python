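"""End-to-end orchestration: proteomes -> hits -> threshold -> pan-genome."""

from __future__ import annotations

from dataclasses import dataclass

from .engine import HitTable, all_vs_all
from .io import ProteomeSet
from .orthology import ThresholdSpec, choose_evalue_threshold
from .pangenome import PanGenome


@dataclass
class PipelineResult:
    proteomes: ProteomeSet
    tables: dict[tuple[str, str], HitTable]
    threshold: ThresholdSpec | float
    pangenome: PanGenome

    @property
    def evalue_threshold(self) -> float:
        return float(self.threshold)


def run_pipeline(pset: ProteomeSet, M: float = 1.0,
                 threshold: float | None = None, n_p: int | None = None,
                 kmer_size: int = 6) -> PipelineResult:
    """All-vs-all similarity, automatic threshold choice, RBH pan-genome.

    ``threshold`` overrides the analytic choice; otherwise the threshold is
    E = M / (n_p^2 * n_o^2) with n_p the largest proteome (overridable for
    conservative rounding) and n_o the number of isolates.
    """
    tables = all_vs_all(pset, kmer_size=kmer_size)
    if threshold is None:
        spec: ThresholdSpec | float = choose_evalue_threshold(
            M, n_p if n_p is not None else pset.n_p, pset.n_o
        )
    else:
        spec = float(threshold)
    pangenome = PanGenome.from_hit_tables(pset, tables, float(spec))
    return PipelineResult(pset, tables, spec, pangenome)
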