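"""Synthetic matched immunopeptidome + proteome datasets with ground truth.

The generator emulates the statistical structure the analysis assumes so
every pipeline stage can be exercised, and falsified, without raw mass
spectrometry data:

* log-normal per-cell protein copies with protein-specific across-sample
  variability, including histones (whose total mass per cell is constructed
  to equal the configured DNA mass exactly, making the proteomic ruler
  invertible) and B2M;
* antigens tied to source proteins through a tunable coupling ``rho``
  between per-sample protein deviations and presentation-efficiency
  deviations (``rho=1``: presentation mirrors expression; ``rho=0``: fully
  decoupled);
* 8-12-mer peptides peaked at length 9 with fixed anchor residues at
  position 2 and the C-terminus;
* measurement rendering: MS response proportional to molecule mass, a
  per-sample global scale factor (unequal fragment sizes / cell input),
  multiplicative log-normal noise, charge/modification precursor splitting,
  left-censored (logistic in log-intensity) plus random missingness, and
  global protein-group q-values exercising the identification filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import AVOGADRO, DNA_MASS_DIPLOID_HUMAN
from .io_formats import PrecursorTable, ProteinRecord, SampleSheet
from .quantify import molar_mass

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_proteome",
    "simulate_immunopeptidome",
    "render_measurements",
    "simulate_dataset",
    "write_dataset",
    "simulate_log2_dataset",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: 15 tumour-fragment-like samples, a 3000-protein
    proteome and a 1500-antigen ligandome, 20% noise CV and left-censored
    missingness targeting ~20% of cells."""

    n_samples: int = 15
    n_proteins: int = 3000
    n_antigens: int = 1500
    frac_histone: float = 0.01
    b2m_copies_mean: float = 5e5
    #: B2M per-sample deviation sd (natural log units); B2M is a constitutive
    #: structural protein and varies less across fragments than immune or
    #: stromal proteins. Because pseudocounts are anchored to B2M, this also
    #: sets the shared component of antigen variability.
    b2m_copies_logsd: float = 0.25
    #: median per-protein across-sample deviation sd (natural log units)
    protein_copies_logsd: float = 0.4
    #: across-protein spread of baseline abundance (natural log units)
    dynamic_range_logsd: float = 2.0
    #: across-antigen spread of baseline presentation (natural log units)
    antigen_logsd: float = 1.5
    #: correlation between protein deviations and presentation deviations
    coupling_rho: float = 0.2
    #: per-sample fragment-size factor, sd of log scale
    input_scale_logsd: float = 0.8
    noise_cv: float = 0.2
    #: detection midpoint as a quantile of the log-intensity distribution
    mnar_midpoint_quantile: float = 0.2
    #: logistic steepness per natural-log-intensity unit
    mnar_slope: float = 4.0
    mar_rate: float = 0.02
    #: fraction of (non-histone, non-B2M) protein groups failing the 1% FDR
    q_fail_frac: float = 0.05
    charge_states: tuple[int, ...] = (1, 2, 3)
    length_weights: tuple[tuple[int, float], ...] = (
        (8, 0.10),
        (9, 0.60),
        (10, 0.15),
        (11, 0.10),
        (12, 0.05),
    )
    anchor_p2: str = "L"
    anchor_cterm: str = "V"
    max_per_protein: int = 5
    dna_mass_per_cell: float = DNA_MASS_DIPLOID_HUMAN
    seed: int = 0

    def __post_init__(self) -> None:
        weights = dict(self.length_weights)
        if abs(sum(weights.values()) - 1.0) > 1e-9:
            raise ValueError("length weights must sum to 1")
        for p in (self.mar_rate, self.mnar_midpoint_quantile, self.q_fail_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.coupling_rho <= 1.0:
            raise ValueError("coupling_rho must lie in [0, 1]")

    def noise_free(self) -> "SimulationConfig":
        """Variant with no measurement noise, missingness or q failures
        (per-sample input scaling stays on: the pipeline must remove it)."""
        return replace(
            self,
            noise_cv=0.0,
            mnar_midpoint_quantile=0.0,
            mar_rate=0.0,
            q_fail_frac=0.0,
        )

    @property
    def samples(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


@dataclass
class ProteomeTruth:
    copies: pd.DataFrame  # accession x sample, true copies per cell
    records: list[ProteinRecord]
    sigma: pd.Series  # per-protein deviation sd
    z: pd.DataFrame  # standardized per-sample deviations
    b2m_accession: str
    histone_accessions: list[str]


@dataclass
class ImmunoTruth:
    pseudocounts: pd.DataFrame  # peptide x sample, true molecules per cell
    source: pd.Series  # peptide -> source accession
    source_gene: pd.Series


@dataclass
class SimulationTruth:
    """Ground truth for recovery tests (copies, pseudocounts, provenance)."""

    config: SimulationConfig
    proteome: ProteomeTruth
    immuno: ImmunoTruth
    scale: pd.Series  # per-sample input scale factor
    missing_class: pd.DataFrame | None = None  # long: table, precursor_id, sample, class

    @property
    def b2m_copies(self) -> pd.Series:
        return self.proteome.copies.loc[self.proteome.b2m_accession]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def simulate_proteome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> ProteomeTruth:
    """Draw true per-cell protein copies and matching protein records.

    Histone copies are rescaled per sample so that the summed histone mass
    equals ``dna_mass_per_cell`` exactly, anchoring the ruler; B2M is added
    with its own configured mean abundance.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_hist = int(round(config.frac_histone * config.n_proteins))
    if n_hist < 1:
        raise ValueError("frac_histone too small: the ruler needs >= 1 histone")
    samples = config.samples

    records: list[ProteinRecord] = []
    families = ["H2AC", "H2BC", "H3C", "H4C"]
    for i in range(n_hist):
        gene = f"{families[i % 4]}{i // 4 + 1}"
        acc = f"SIMH{i + 1:04d}"
        seq = _random_sequence(rng, int(rng.integers(120, 150)))
        records.append(ProteinRecord(acc, gene, seq, is_histone=True))
    b2m_acc = "SIMB0001"
    records.append(ProteinRecord(b2m_acc, "B2M", _random_sequence(rng, 119), is_histone=False))
    n_other = config.n_proteins - n_hist - 1
    if n_other < 0:
        raise ValueError("n_proteins too small for histones + B2M")
    for i in range(n_other):
        acc = f"SIMP{i + 1:05d}"
        gene = f"GENE{i + 1:05d}"
        seq = _random_sequence(rng, int(rng.integers(100, 600)))
        records.append(ProteinRecord(acc, gene, seq, is_histone=False))

    accs = [r.accession for r in records]
    n = len(records)
    # Baseline abundance and protein-specific variability.
    mu = np.log(2e4) + rng.normal(0.0, config.dynamic_range_logsd, size=n)
    mu[accs.index(b2m_acc)] = np.log(config.b2m_copies_mean)
    # Histones are abundant before the exact per-sample mass rescaling.
    for i in range(n_hist):
        mu[i] = np.log(1e6) + rng.normal(0.0, 0.2)
    sigma = np.exp(np.log(config.protein_copies_logsd) + rng.normal(0.0, 0.5, size=n)) \
        if config.protein_copies_logsd > 0 else np.zeros(n)
    if config.protein_copies_logsd > 0:
        sigma[accs.index(b2m_acc)] = config.b2m_copies_logsd
    z = rng.standard_normal((n, config.n_samples))
    log_copies = mu[:, None] + sigma[:, None] * z
    copies = np.exp(log_copies)

    # Enforce sum_h copies_h * M_h / N_A == dna_mass_per_cell per sample.
    masses = np.array([molar_mass(r.sequence) for r in records])
    hist_idx = np.arange(n_hist)
    hist_mass = (copies[hist_idx] * masses[hist_idx, None]).sum(axis=0) / AVOGADRO
    factor = config.dna_mass_per_cell / hist_mass
    copies[hist_idx] *= factor[None, :]

    copies_df = pd.DataFrame(copies, index=pd.Index(accs, name="accession"), columns=samples)
    return ProteomeTruth(
        copies=copies_df,
        records=records,
        sigma=pd.Series(sigma, index=accs),
        z=pd.DataFrame(z, index=accs, columns=samples),
        b2m_accession=b2m_acc,
        histone_accessions=[r.accession for r in records if r.is_histone],
    )


def _draw_peptides(config: SimulationConfig, rng: np.random.Generator, n: int) -> list[str]:
    lengths, weights = zip(*config.length_weights)
    out: set[str] = set()
    while len(out) < n:
        L = int(rng.choice(lengths, p=weights))
        seq = list(_random_sequence(rng, L))
        seq[1] = config.anchor_p2
        seq[-1] = config.anchor_cterm
        out.add("".join(seq))
    return sorted(out)[:n] if len(out) == n else list(out)[:n]


def simulate_immunopeptidome(
    config: SimulationConfig,
    proteome: ProteomeTruth,
    rng: np.random.Generator | None = None,
) -> ImmunoTruth:
    """Draw true antigen pseudocounts tied to the proteome through ``rho``.

    Per antigen ``j`` with source protein ``i``, the per-sample log
    presentation deviation is ``tau_j * (rho * z_i + sqrt(1-rho^2) * eta)``
    with ``tau_j = rho * sigma_i + (1-rho) * tau_ind``: at ``rho=1`` the
    antigen reproduces the source protein's deviations exactly (pattern and
    magnitude); at ``rho=0`` both are independent of the proteome.
    Pseudocounts are normalised so each sample's total equals its true B2M
    copy number (one B2M per surface complex).
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    eligible = [
        r.accession
        for r in proteome.records
        if not r.is_histone and r.accession != proteome.b2m_accession
    ]
    if config.n_antigens > len(eligible) * config.max_per_protein:
        raise ValueError(
            f"cannot place {config.n_antigens} antigens on {len(eligible)} proteins "
            f"(max {config.max_per_protein} each)"
        )
    pool = np.repeat(eligible, config.max_per_protein)
    source = rng.permutation(pool)[: config.n_antigens]
    peptides = _draw_peptides(config, rng, config.n_antigens)

    rho = config.coupling_rho
    sigma_src = proteome.sigma.loc[source].to_numpy()
    z_src = proteome.z.loc[source].to_numpy()
    tau_ind = (
        np.exp(np.log(config.protein_copies_logsd) + rng.normal(0.0, 0.5, size=config.n_antigens))
        if config.protein_copies_logsd > 0
        else np.zeros(config.n_antigens)
    )
    tau = rho * sigma_src + (1.0 - rho) * tau_ind
    eta = rng.standard_normal((config.n_antigens, config.n_samples))
    eps = tau[:, None] * (rho * z_src + np.sqrt(1.0 - rho**2) * eta)
    nu = rng.normal(0.0, config.antigen_logsd, size=config.n_antigens)
    raw = np.exp(nu[:, None] + eps)

    b2m = proteome.copies.loc[proteome.b2m_accession].to_numpy()
    pseudo = raw / raw.sum(axis=0, keepdims=True) * b2m[None, :]

    gene_of = {r.accession: r.gene for r in proteome.records}
    idx = pd.Index(peptides, name="peptide")
    return ImmunoTruth(
        pseudocounts=pd.DataFrame(pseudo, index=idx, columns=config.samples),
        source=pd.Series(source, index=idx, name="source_accession"),
        source_gene=pd.Series([gene_of[a] for a in source], index=idx, name="gene"),
    )


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv <= 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=shape))


def _apply_missingness(
    intens: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Return a class matrix ('observed'/'MNAR'/'MAR') for positive cells."""
    cls = np.full(intens.shape, "observed", dtype=object)
    with np.errstate(divide="ignore"):
        logi = np.log(intens)
    if config.mnar_midpoint_quantile > 0:
        from scipy.special import expit

        mid = np.quantile(logi[np.isfinite(logi)], config.mnar_midpoint_quantile)
        p_detect = expit(config.mnar_slope * (logi - mid))
        cls[rng.random(intens.shape) > p_detect] = "MNAR"
    if config.mar_rate > 0:
        mar = (rng.random(intens.shape) < config.mar_rate) & (cls == "observed")
        cls[mar] = "MAR"
    return cls


def _split_precursors(
    rng: np.random.Generator,
    n_variants: np.ndarray,
) -> list[np.ndarray]:
    """Random precursor proportions per feature, fixed across samples.

    Dirichlet(2,..,2): moderately uneven, like typical charge-state
    distributions (dominant variant a few-fold above the weakest), while
    keeping measurement noise distributed over the variants.
    """
    return [rng.dirichlet(np.full(k, 2.0)) for k in n_variants]


def render_measurements(
    truth: SimulationTruth, rng: np.random.Generator | None = None
) -> tuple[PrecursorTable, PrecursorTable]:
    """Render ground truth into wide search-engine-style precursor tables.

    Returns ``(immunopeptidome, proteome)`` precursor tables; the observed
    missing-class bookkeeping is stored on ``truth.missing_class``.
    """
    config = truth.config
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    samples = config.samples
    scale = truth.scale.to_numpy()

    mass_of = {r.accession: molar_mass(r.sequence) for r in truth.proteome.records}
    gene_of = {r.accession: r.gene for r in truth.proteome.records}
    protected = set(truth.proteome.histone_accessions) | {truth.proteome.b2m_accession}

    missing_rows = []

    def q_values(ids: list[str], protected_ids: set[str]) -> dict[str, float]:
        qs = {}
        eligible = [i for i in ids if i not in protected_ids]
        n_fail = int(round(config.q_fail_frac * len(eligible)))
        fail = set(rng.choice(eligible, size=n_fail, replace=False)) if n_fail else set()
        for i in ids:
            qs[i] = float(rng.uniform(0.011, 0.2)) if i in fail else float(rng.uniform(0.0, 0.009))
        return qs

    # ---- proteome: MS response proportional to protein mass ----------------
    accs = list(truth.proteome.copies.index)
    copies = truth.proteome.copies.to_numpy()
    masses = np.array([mass_of[a] for a in accs])
    base = copies * masses[:, None] * scale[None, :] * 1e-3
    # Peptide detection is abundance-dependent: abundant proteins (histones,
    # B2M) are quantified from many precursors, low-abundance ones from few.
    rel = np.log10(np.median(base, axis=1) / np.median(base))
    n_prec = np.clip(
        np.round(5 + 1.5 * rel).astype(int) + rng.integers(-1, 2, size=len(accs)), 2, 10
    )
    props = _split_precursors(rng, n_prec)
    qs = q_values(accs, protected)

    rows = []
    intens_rows = []
    for i, acc in enumerate(accs):
        for k in range(n_prec[i]):
            pep = f"{acc}PEP{k + 1}"  # placeholder tryptic peptide id
            seq = _random_sequence(rng, int(rng.integers(8, 20)))
            charge = int(rng.choice((2, 3)))
            rows.append(
                (
                    f"{acc}.{k + 1}.{charge}",
                    seq,
                    seq,
                    charge,
                    acc,
                    gene_of[acc],
                    qs[acc],
                )
            )
            noise = _lognormal_noise(rng, config.noise_cv, config.n_samples)
            intens_rows.append(base[i] * props[i][k] * noise)
    prot_intens = np.array(intens_rows)
    prot_cls = _apply_missingness(prot_intens, config, rng)
    # Never censor the anchor proteins: histones and B2M are among the most
    # abundant proteins in any cell and are always confidently quantified.
    for r, row in enumerate(rows):
        if row[4] in protected:
            prot_cls[r, :] = "observed"
    prot_obs = np.where(prot_cls == "observed", prot_intens, np.nan)

    proteome_df = pd.DataFrame(
        rows,
        columns=[
            "precursor_id",
            "stripped_sequence",
            "modified_sequence",
            "charge",
            "protein_group",
            "gene",
            "pg_q_value",
        ],
    )
    for j, s in enumerate(samples):
        proteome_df[s] = prot_obs[:, j]
    for r, row in enumerate(rows):
        for j, s in enumerate(samples):
            if prot_cls[r, j] != "observed":
                missing_rows.append(("proteome", row[0], s, prot_cls[r, j]))

    # ---- immunopeptidome: response proportional to molecule count ----------
    peptides = list(truth.immuno.pseudocounts.index)
    pseudo = truth.immuno.pseudocounts.to_numpy()
    pep_base = pseudo * scale[None, :] * 1.0
    n_var = rng.integers(1, 4, size=len(peptides))
    pep_props = _split_precursors(rng, n_var)
    pep_qs = q_values(peptides, set())

    prows = []
    pintens = []
    mods = ["", "[Oxidation]", "[Acetyl]"]
    for i, pep in enumerate(peptides):
        charges = rng.permutation(config.charge_states)
        for k in range(n_var[i]):
            charge = int(charges[k % len(config.charge_states)])
            mod = mods[k % len(mods)]
            modseq = pep + mod
            prows.append(
                (
                    f"{modseq}.{charge}",
                    pep,
                    modseq,
                    charge,
                    truth.immuno.source.loc[pep],
                    truth.immuno.source_gene.loc[pep],
                    pep_qs[pep],
                )
            )
            noise = _lognormal_noise(rng, config.noise_cv, config.n_samples)
            pintens.append(pep_base[i] * pep_props[i][k] * noise)
    pep_intens = np.array(pintens)
    pep_cls = _apply_missingness(pep_intens, config, rng)
    pep_obs = np.where(pep_cls == "observed", pep_intens, np.nan)

    immuno_df = pd.DataFrame(prows, columns=list(proteome_df.columns[:7]))
    for j, s in enumerate(samples):
        immuno_df[s] = pep_obs[:, j]
    for r, row in enumerate(prows):
        for j, s in enumerate(samples):
            if pep_cls[r, j] != "observed":
                missing_rows.append(("immunopeptidome", row[0], s, pep_cls[r, j]))

    truth.missing_class = pd.DataFrame(
        missing_rows, columns=["table", "precursor_id", "sample", "class"]
    )
    immuno_table = PrecursorTable(immuno_df, samples)
    proteome_table = PrecursorTable(proteome_df, samples)
    return immuno_table, proteome_table


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[SimulationTruth, PrecursorTable, PrecursorTable]:
    """One-call generation: truth plus rendered precursor tables."""
    rng = np.random.default_rng(config.seed)
    proteome = simulate_proteome(config, rng)
    immuno = simulate_immunopeptidome(config, proteome, rng)
    scale = pd.Series(
        np.exp(rng.normal(0.0, config.input_scale_logsd, size=config.n_samples)),
        index=config.samples,
        name="scale",
    )
    truth = SimulationTruth(config=config, proteome=proteome, immuno=immuno, scale=scale)
    immuno_table, proteome_table = render_measurements(truth, rng)
    return truth, immuno_table, proteome_table


def write_dataset(
    truth: SimulationTruth,
    immuno_table: PrecursorTable,
    proteome_table: PrecursorTable,
    outdir: str | Path,
    condition_split: bool = False,
) -> dict[str, Path]:
    """Emit the dataset as DIA-style TSV + FASTA + sample sheet + truth tables."""
    from .io_formats import DEFAULT_DIALECT

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rename = {k: v for k, v in DEFAULT_DIALECT.items()}
    for name, table in (("immunopeptidome", immuno_table), ("proteome", proteome_table)):
        df = table.data.rename(columns=rename)
        p = outdir / f"{name}_precursors.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.17g", na_rep="")
        paths[name] = p

    fasta = outdir / "proteins.fasta"
    with open(fasta, "w") as fh:
        for r in truth.proteome.records:
            fh.write(f">sp|{r.accession}|{r.accession}_SIM synthetic protein GN={r.gene}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")
    paths["fasta"] = fasta

    samples = truth.config.samples
    half = len(samples) // 2
    sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "condition": (
                ["A"] * half + ["B"] * (len(samples) - half)
                if condition_split
                else ["fragment"] * len(samples)
            ),
            "replicate": (
                list(range(1, half + 1)) + list(range(1, len(samples) - half + 1))
                if condition_split
                else list(range(1, len(samples) + 1))
            ),
        }
    )
    paths["sample_sheet"] = outdir / "sample_sheet.tsv"
    sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)

    for name, df in (
        ("truth_copies", truth.proteome.copies),
        ("truth_pseudocounts", truth.immuno.pseudocounts),
    ):
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", float_format="%.17g")
        paths[name] = p
    paths["truth_scale"] = outdir / "truth_scale.tsv"
    truth.scale.to_frame().to_csv(paths["truth_scale"], sep="\t")
    return paths


def simulate_log2_dataset(
    n_features: int,
    n_per_group: int,
    effect_size: float = 0.0,
    frac_changed: float = 0.0,
    base_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, SampleSheet, pd.Series]:
    """Simple two-condition log2 matrix for testing calibration and power.

    ``effect_size`` (log2 units) is added to condition B for a random
    ``frac_changed`` subset of features. Returns (matrix, sample sheet,
    boolean truth of changed features).
    """
    rng = np.random.default_rng(seed)
    samples = [f"A{i + 1}" for i in range(n_per_group)] + [
        f"B{i + 1}" for i in range(n_per_group)
    ]
    base = rng.normal(20.0, 2.0, size=n_features)
    data = base[:, None] + rng.normal(0.0, base_sd, size=(n_features, 2 * n_per_group))
    changed = np.zeros(n_features, dtype=bool)
    n_changed = int(round(frac_changed * n_features))
    if n_changed:
        idx = rng.choice(n_features, size=n_changed, replace=False)
        changed[idx] = True
        sign = rng.choice([-1.0, 1.0], size=n_changed)
        data[idx, n_per_group:] += sign[:, None] * effect_size
    index = pd.Index([f"feat{i + 1}" for i in range(n_features)], name="feature")
    matrix = pd.DataFrame(data, index=index, columns=samples)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": samples,
                "condition": ["A"] * n_per_group + ["B"] * n_per_group,
                "replicate": list(range(1, n_per_group + 1)) * 2,
            }
        )
    )
    return matrix, sheet, pd.Series(changed, index=index, name="changed")
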