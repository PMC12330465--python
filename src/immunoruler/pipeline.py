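"""End-to-end orchestration: simulate/read -> quantify -> QC -> heterogeneity.

`analyze_tables` is the in-memory core used by tests and simulations;
`run_pipeline` adds file IO, a YAML-style config, per-stage logging and a
machine-readable summary with the config hash and conservation residuals.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .heterogeneity import (
    map_antigen_to_protein,
    per_sample_concordance,
    variability_concordance,
    variability_score,
)
from .io_formats import (
    PrecursorTable,
    ProteinRecord,
    SampleSheet,
    read_fasta_proteins,
    read_precursor_matrix,
    read_sample_sheet,
    write_matrix_tsv,
)
from .qc import anchor_enrichment, length_distribution, position_frequency_matrix
from .quantify import (
    CopyNumberMatrix,
    PseudocountMatrix,
    aggregate_precursors,
    b2m_pseudocounts,
    filter_by_pg_q_value,
    proteomic_ruler,
)

__all__ = ["AnalysisResult", "analyze_tables", "run_pipeline", "config_hash"]


@dataclass
class AnalysisResult:
    pseudocounts: PseudocountMatrix
    copies: CopyNumberMatrix
    n_precursors_in: dict[str, int]
    n_precursors_kept: dict[str, int]

    @property
    def conservation_residual(self) -> float:
        """Max relative deviation of per-sample pseudocount totals from B2M."""
        total = self.pseudocounts.pseudocounts.sum(axis=0, skipna=True)
        return float((total / self.pseudocounts.b2m_copies - 1.0).abs().max())


def analyze_tables(
    immuno: PrecursorTable,
    proteome: PrecursorTable,
    records: Sequence[ProteinRecord],
    q_threshold: float = 0.01,
    dna_mass_per_cell: float | None = None,
    peptide_key: str = "stripped",
    cross_sample_mean_b2m: bool = False,
    b2m: str = "B2M",
) -> AnalysisResult:
    """Run q-filter -> aggregation -> ruler -> B2M anchoring in memory."""
    from .constants import DNA_MASS_DIPLOID_HUMAN

    n_in = {"immunopeptidome": immuno.n_rows, "proteome": proteome.n_rows}
    immuno_f = filter_by_pg_q_value(immuno, q_threshold)
    proteome_f = filter_by_pg_q_value(proteome, q_threshold)
    n_kept = {"immunopeptidome": immuno_f.n_rows, "proteome": proteome_f.n_rows}

    antigens = aggregate_precursors(immuno_f, key=peptide_key)
    protein_groups = aggregate_precursors(proteome_f, key="protein_group")
    copies = proteomic_ruler(
        protein_groups,
        records,
        dna_mass_per_cell=dna_mass_per_cell or DNA_MASS_DIPLOID_HUMAN,
    )
    pseudo = b2m_pseudocounts(antigens, copies, b2m=b2m, cross_sample_mean=cross_sample_mean_b2m)
    return AnalysisResult(
        pseudocounts=pseudo,
        copies=copies,
        n_precursors_in=n_in,
        n_precursors_kept=n_kept,
    )


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping (identifies every output)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


DEFAULT_CONFIG: dict = {
    "inputs": {
        "immunopeptidome": None,
        "proteome": None,
        "fasta": None,
        "sample_sheet": None,
    },
    "simulate": None,  # mapping of SimulationConfig overrides, or None
    "thresholds": {"pg_q": 0.01, "affinity_nM": 100.0, "alpha": 0.05, "lfc": 1.0,
                   "min_samples": 8},
    "constants": {"dna_mass_per_cell": 6.5e-12, "shift": 1.8, "width": 0.3, "knn_k": 10},
    "peptide_key": "stripped",
    "b2m": "B2M",
    "seed": 0,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the full pipeline described by ``config`` into ``outdir``.

    When ``config['simulate']`` is set, a synthetic dataset is generated
    first and analysed in place of user inputs. Every intermediate table is
    written as TSV; the returned (and written) summary carries stage counts,
    the conservation residual and the config hash.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    summary: dict = {"tool": "immunoruler", "version": __version__, "config_hash": chash}

    if config.get("simulate") is not None:
        from .simulate import SimulationConfig, simulate_dataset, write_dataset

        sim_kwargs = dict(config["simulate"] or {})
        sim_kwargs.setdefault("seed", config.get("seed", 0))
        sim_cfg = SimulationConfig(**sim_kwargs)
        truth, immuno_tab, proteome_tab = simulate_dataset(sim_cfg)
        simdir = outdir / "simulated"
        write_dataset(truth, immuno_tab, proteome_tab, simdir)
        records = truth.proteome.records
        sheet = read_sample_sheet(simdir / "sample_sheet.tsv")
        summary["simulate"] = {"n_samples": sim_cfg.n_samples, "seed": sim_cfg.seed}
    else:
        inputs = config["inputs"]
        for key in ("immunopeptidome", "proteome", "fasta", "sample_sheet"):
            if not inputs.get(key):
                raise FileNotFoundError(f"config inputs.{key} not set")
            if not Path(inputs[key]).exists():
                raise FileNotFoundError(f"input file missing: {inputs[key]}")
        sheet = read_sample_sheet(inputs["sample_sheet"])
        immuno_tab = read_precursor_matrix(inputs["immunopeptidome"], sheet)
        proteome_tab = read_precursor_matrix(inputs["proteome"], sheet)
        records = read_fasta_proteins(inputs["fasta"])

    result = analyze_tables(
        immuno_tab,
        proteome_tab,
        records,
        q_threshold=config["thresholds"]["pg_q"],
        dna_mass_per_cell=config["constants"]["dna_mass_per_cell"],
        peptide_key=config.get("peptide_key", "stripped"),
        b2m=config.get("b2m", "B2M"),
    )
    write_matrix_tsv(result.copies.copies, outdir / "copies_per_cell.tsv", "protein_group")
    write_matrix_tsv(result.pseudocounts.pseudocounts, outdir / "pseudocounts_per_cell.tsv",
                     "antigen")
    write_matrix_tsv(result.pseudocounts.fraction, outdir / "antigen_fractions.tsv", "antigen")
    result.pseudocounts.b2m_copies.to_frame("b2m_copies").to_csv(
        outdir / "b2m_copies.tsv", sep="\t", float_format="%.17g"
    )

    peptides = list(result.pseudocounts.pseudocounts.index)
    ld = length_distribution(peptides)
    ld.counts.to_frame("count").to_csv(outdir / "length_distribution.tsv", sep="\t")
    qc_summary = {"n_peptides": ld.total, "fraction_length9": ld.fraction_length9}
    try:
        pfm = position_frequency_matrix(peptides, 9)
        pfm.freq.to_csv(outdir / "pfm_9mer.tsv", sep="\t", float_format="%.6g")
        qc_summary["anchor_enrichment_bits"] = anchor_enrichment(pfm)
    except ValueError:
        qc_summary["anchor_enrichment_bits"] = None
    summary["qc"] = qc_summary

    min_samples = int(config["thresholds"]["min_samples"])
    antigen_var = variability_score(result.pseudocounts, min_samples=min_samples)
    protein_var = variability_score(result.copies, min_samples=min_samples)
    antigen_var.to_csv(outdir / "antigen_variability.tsv", sep="\t", float_format="%.10g")
    protein_var.to_csv(outdir / "protein_variability.tsv", sep="\t", float_format="%.10g")
    mapping = map_antigen_to_protein(result.pseudocounts.feature_meta, result.copies)
    het: dict = {}
    try:
        pairs, stats = variability_concordance(antigen_var, protein_var, mapping)
        pairs.to_csv(outdir / "variability_pairs.tsv", sep="\t", float_format="%.10g")
        het["variability_concordance"] = stats
    except ValueError as exc:
        het["variability_concordance"] = str(exc)
    report = per_sample_concordance(result.pseudocounts, result.copies, mapping)
    pd.DataFrame({"pearson_r": report.per_sample_r, "n_pairs": report.n_pairs}).to_csv(
        outdir / "per_sample_concordance.tsv", sep="\t", float_format="%.10g"
    )
    het["per_sample_r_median"] = (
        float(report.per_sample_r.median()) if report.per_sample_r.notna().any() else None
    )
    summary["heterogeneity"] = het

    summary["counts"] = {
        "precursors_in": result.n_precursors_in,
        "precursors_kept": result.n_precursors_kept,
        "antigens": int(result.pseudocounts.pseudocounts.shape[0]),
        "protein_groups": int(result.copies.copies.shape[0]),
    }
    summary["conservation_residual"] = result.conservation_residual

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
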