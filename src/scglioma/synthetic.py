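"""Ground-truth-labeled synthetic tumors.

Emulates the statistical structure the downstream analysis assumes: a
mixture of transformed subpopulations carrying whole-chromosome
aneuploidies (the classic chr7 gain / chr10 loss of GBM) plus diploid
microenvironment populations (myeloid, T cell, endothelial, pericyte,
oligodendrocyte); lineage marker programs (astrocyte / OPC /
oligodendrocyte / neuroblast); shallow-sampling drop-out from count
sampling at a fixed target depth; and read-level synthesis of 12-nt cell
barcodes and 8-nt UMIs with truncation, substitution, and ambient
cross-contamination errors.

Per-gene molecule counts are Poisson by default (optionally
gamma-overdispersed, i.e. negative binomial) with rate

    base_rate(gene) * marker_program(gene) * copy_number(chrom)/2,

normalized per cell to the target depth. All randomness flows from a
single integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import _seq
from .io import ExpressionMatrix

AUTOSOMES = tuple(str(i) for i in range(1, 23))
BARCODE_LENGTH = 12
UMI_LENGTH = 8


# --------------------------------------------------------------------------
# genome and population models
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    """Gene universe: identifiers, chromosome assignment, HLA flags.

    Mitochondrial genes are those on chromosome "MT". HLA-flagged genes
    must lie on chromosome 6 (they are excluded from chromosome-scale
    expression because HLA copy number is confounded with myeloid
    expression).
    """

    genes: tuple[str, ...]
    chromosome_of: Mapping[str, str]
    hla_flag: Mapping[str, bool]
    cell_cycle_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for g in self.genes:
            if g not in self.chromosome_of:
                raise ValueError(f"gene {g} has no chromosome assignment")
        for g, flag in self.hla_flag.items():
            if flag and self.chromosome_of[g] != "6":
                raise ValueError(f"HLA-flagged gene {g} is not on chromosome 6")

    @property
    def genes_per_chromosome(self) -> pd.Series:
        chroms = pd.Series([self.chromosome_of[g] for g in self.genes])
        return chroms.value_counts()

    def is_mito(self, gene: str) -> bool:
        return self.chromosome_of[gene] == "MT"

    def annotation(self) -> pd.DataFrame:
        """Gene annotation table: chromosome, is_mito, is_hla."""
        chrom = [self.chromosome_of[g] for g in self.genes]
        return pd.DataFrame(
            {
                "chromosome": chrom,
                "is_mito": [c == "MT" for c in chrom],
                "is_hla": [bool(self.hla_flag.get(g, False)) for g in self.genes],
            },
            index=pd.Index(self.genes, name="gene"),
        )

    @classmethod
    def default(
        cls,
        genes_per_autosome: int = 100,
        n_mito: int = 20,
        n_hla: int = 10,
        n_cell_cycle: int = 20,
    ) -> "GenomeModel":
        """Desk-scale genome: uniform autosomes, MT genes, HLA block on chr6.

        100 genes per autosome keeps chromosome averages stable while the
        whole matrix stays small; the cell-cycle program is one gene from
        each of the first `n_cell_cycle` autosome slots on chromosome 1.
        """
        genes: list[str] = []
        chrom_of: dict[str, str] = {}
        hla: dict[str, bool] = {}
        for c in AUTOSOMES:
            for i in range(genes_per_autosome):
                if c == "6" and i < n_hla:
                    name = f"HLA_{i:03d}"
                    hla[name] = True
                else:
                    name = f"G{c}_{i:03d}"
                genes.append(name)
                chrom_of[name] = c
        for i in range(n_mito):
            name = f"MT_{i:03d}"
            genes.append(name)
            chrom_of[name] = "MT"
        cc = tuple(f"G1_{i:03d}" for i in range(50, 50 + n_cell_cycle))
        return cls(tuple(genes), chrom_of, hla, cc)


@dataclass(frozen=True)
class PopulationSpec:
    """One cell population of the mixture.

    copy_number maps chromosome -> integer copies (missing = 2, diploid);
    marker_program maps gene -> relative rate multiplier (missing = 1).
    """

    name: str
    fraction: float
    copy_number: Mapping[str, int] = field(default_factory=dict)
    marker_program: Mapping[str, float] = field(default_factory=dict)
    cycling_fraction: float = 0.0
    is_transformed: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"population {self.name}: fraction outside [0,1]")
        if any(c < 0 for c in self.copy_number.values()):
            raise ValueError(f"population {self.name}: negative copy number")
        if any(r < 0 for r in self.marker_program.values()):
            raise ValueError(f"population {self.name}: negative marker rate")
        if not 0.0 <= self.cycling_fraction <= 1.0:
            raise ValueError(f"population {self.name}: cycling_fraction outside [0,1]")


@dataclass(frozen=True)
class ErrorModel:
    """Read-level error rates injected at molecule-table emission."""

    truncation_rate: float = 0.0  # fraction of cells with 11-nt synthesized barcodes
    umi_substitution_rate: float = 0.0  # per-UMI chance some reads carry a 1-nt sub
    barcode_substitution_rate: float = 0.0  # per-read chance of a 1-nt barcode sub
    cross_contamination_rate: float = 0.0  # fraction of molecules from ambient pool

    def __post_init__(self) -> None:
        for name in (
            "truncation_rate",
            "umi_substitution_rate",
            "barcode_substitution_rate",
            "cross_contamination_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0,1]")


@dataclass
class GroundTruth:
    """Truth labels linking every emitted molecule back to its origin."""

    population: pd.Series  # cell -> population name
    is_transformed: pd.Series  # cell -> bool
    copy_number: pd.DataFrame  # cells x chromosomes, integer copies
    barcode_of: pd.Series | None = None  # cell -> synthesized barcode (11 or 12 nt)
    molecules: pd.DataFrame | None = None  # one row per true molecule

    @property
    def cells(self) -> pd.Index:
        return self.population.index


# --------------------------------------------------------------------------
# expression simulation
# --------------------------------------------------------------------------

def gene_base_rates(genome: GenomeModel, seed: int) -> pd.Series:
    """Log-normal per-gene baseline rates (sigma=1), deterministic in seed."""
    rng = np.random.default_rng(seed)
    rates = rng.lognormal(mean=0.0, sigma=1.0, size=len(genome.genes))
    return pd.Series(rates, index=pd.Index(genome.genes, name="gene"))


def simulate_expression(
    genome: GenomeModel,
    populations: Sequence[PopulationSpec],
    n_cells: int,
    depth: float,
    seed: int,
    base_rates: pd.Series | None = None,
    dispersion: float | None = None,
    cycling_boost: float = 4.0,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Sample a genes x cells molecule-count matrix plus ground truth.

    Per-cell rates are base * marker_program * (copies/2) on the gene's
    chromosome (MT held at 2 copies), normalized so the expected cell
    depth equals `depth`. Counts are Poisson, or negative binomial when
    `dispersion` (gamma shape = 1/dispersion) is given.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    if depth <= 0:
        raise ValueError("depth must be positive")
    fractions = np.array([p.fraction for p in populations], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-8:
        raise ValueError(
            f"population fractions sum to {fractions.sum():.6f}, expected 1"
        )
    rng = np.random.default_rng(seed)
    if base_rates is None:
        base = rng.lognormal(mean=0.0, sigma=1.0, size=len(genome.genes))
    else:
        base = base_rates.reindex(genome.genes).to_numpy(dtype=float)

    # largest-remainder apportionment of cells to populations
    raw = fractions * n_cells
    n_per = np.floor(raw).astype(int)
    short = n_cells - n_per.sum()
    if short:
        order = np.argsort(-(raw - n_per), kind="stable")
        n_per[order[:short]] += 1

    chrom = np.array([genome.chromosome_of[g] for g in genome.genes])
    cc_mask = np.isin(np.array(genome.genes), np.array(genome.cell_cycle_genes))

    cells = pd.Index(
        [f"cell{i:05d}" for i in range(n_cells)], name="cell"
    )
    counts = np.zeros((len(genome.genes), n_cells), dtype=np.int64)
    pop_labels = np.empty(n_cells, dtype=object)
    transformed = np.zeros(n_cells, dtype=bool)
    cn_rows = np.full((n_cells, len(AUTOSOMES)), 2, dtype=int)

    start = 0
    for spec, n_pop in zip(populations, n_per):
        if n_pop == 0:
            continue
        stop = start + n_pop
        dosage = np.array(
            [spec.copy_number.get(c, 2) / 2.0 if c != "MT" else 1.0 for c in chrom]
        )
        marker = np.array([spec.marker_program.get(g, 1.0) for g in genome.genes])
        rate = base * marker * dosage
        if rate.sum() == 0:
            raise ValueError(f"population {spec.name}: all-zero expression rates")
        cycling = rng.random(n_pop) < spec.cycling_fraction
        for j in range(n_pop):
            r = rate.copy()
            if cycling[j]:
                r[cc_mask] *= cycling_boost
            lam = r / r.sum() * depth
            if dispersion:
                shape = 1.0 / dispersion
                lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
            counts[:, start + j] = rng.poisson(lam)
        pop_labels[start:stop] = spec.name
        transformed[start:stop] = spec.is_transformed
        for ci, c in enumerate(AUTOSOMES):
            cn_rows[start:stop, ci] = spec.copy_number.get(c, 2)
        start = stop

    expr = ExpressionMatrix(sp.csr_matrix(counts), pd.Index(genome.genes), cells)
    truth = GroundTruth(
        population=pd.Series(pop_labels, index=cells, name="population"),
        is_transformed=pd.Series(transformed, index=cells, name="is_transformed"),
        copy_number=pd.DataFrame(cn_rows, index=cells, columns=list(AUTOSOMES)),
    )
    return expr, truth


# --------------------------------------------------------------------------
# molecule-table emission with injected errors
# --------------------------------------------------------------------------

def _assign_umis(rng: np.random.Generator, group_ids: np.ndarray) -> np.ndarray:
    """Distinct, pairwise Hamming>=2 UMI codes within each group.

    `group_ids` must be sorted. Distance >= 2 within a (cell, gene) group
    guarantees an error-free table collapses back to the source matrix
    exactly (Hamming-1 UMI collapse merges nothing it should not).
    """
    n = len(group_ids)
    umis = _seq.random_codes(rng, n, UMI_LENGTH)
    boundaries = np.flatnonzero(np.diff(group_ids)) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [n]))
    for s, t in zip(starts, stops):
        if t - s == 1:
            continue
        accepted: list[int] = []
        for i in range(s, t):
            code = int(umis[i])
            while any(_seq.hamming(code, a) <= 1 for a in accepted):
                code = int(rng.integers(0, 4**UMI_LENGTH))
            umis[i] = code
            accepted.append(code)
    return umis


def emit_molecule_table(
    expr: ExpressionMatrix,
    truth: GroundTruth,
    errors: ErrorModel,
    reads_per_molecule: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Synthesize a read-level molecule table from an expression matrix.

    Returns the table (one row per observed (barcode, umi, gene) with a
    read count) and the ground truth updated with per-cell synthesized
    barcodes and the molecule-level truth table. Truncated cells carry the
    paper-described signature: an 11-nt synthesized barcode whose record
    field borrows the UMI's first base, shifting the UMI so its terminal
    base reads 'T'.
    """
    if reads_per_molecule < 1:
        raise ValueError("reads_per_molecule must be >= 1")
    rng = np.random.default_rng(seed)
    n_cells = len(expr.cells)

    barcode_codes = _seq.spaced_codes(rng, n_cells, BARCODE_LENGTH, min_dist=3)
    barcode_strs = _seq.decode_array(barcode_codes, BARCODE_LENGTH)
    truncated = rng.random(n_cells) < errors.truncation_rate

    coo = sp.coo_matrix(expr.counts)
    reps = coo.data.astype(int)
    gene_idx = np.repeat(coo.row, reps)
    cell_idx = np.repeat(coo.col, reps)
    order = np.argsort(cell_idx * len(expr.genes) + gene_idx, kind="stable")
    gene_idx = gene_idx[order]
    cell_idx = cell_idx[order]
    n_mol = len(gene_idx)

    # ambient cross-contamination: molecule's gene swapped for a pooled draw
    if errors.cross_contamination_rate > 0:
        pooled = expr.gene_totals().to_numpy(dtype=float)
        pooled = pooled / pooled.sum()
        swap = rng.random(n_mol) < errors.cross_contamination_rate
        gene_idx = gene_idx.copy()
        gene_idx[swap] = rng.choice(len(expr.genes), size=int(swap.sum()), p=pooled)

    group = cell_idx.astype(np.int64) * len(expr.genes) + gene_idx
    regroup = np.argsort(group, kind="stable")
    gene_idx = gene_idx[regroup]
    cell_idx = cell_idx[regroup]
    umi_codes = _assign_umis(rng, group[regroup])

    genes_arr = np.asarray(expr.genes)
    # truncated cells exist downstream under their 11-nt synthesized barcode
    truth_barcodes = np.array(
        [b[:11] if t else b for b, t in zip(barcode_strs, truncated)], dtype=object
    )

    umi_strs = _seq.decode_array(umi_codes, UMI_LENGTH)
    molecules = pd.DataFrame(
        {
            "cell": np.asarray(expr.cells)[cell_idx],
            "barcode": truth_barcodes[cell_idx],
            "umi": umi_strs,
            "gene": genes_arr[gene_idx],
        }
    )

    reads = 1 + rng.poisson(max(reads_per_molecule - 1.0, 0.0), size=n_mol)

    # emitted 12-nt barcode field and 8-nt UMI field per molecule
    emit_bc = np.array(
        [
            b[:11] + u[0] if t else b
            for b, u, t in zip(
                barcode_strs[cell_idx], umi_strs, truncated[cell_idx]
            )
        ],
        dtype=object,
    )
    emit_umi = np.array(
        [
            u[1:] + "T" if t else u
            for u, t in zip(umi_strs, truncated[cell_idx])
        ],
        dtype=object,
    )

    rows_bc: list[np.ndarray] = []
    rows_umi: list[np.ndarray] = []
    rows_gene: list[np.ndarray] = []
    rows_reads: list[np.ndarray] = []

    reads_main = reads.copy()

    # UMI substitution: with per-molecule probability, >= 1 read carries a
    # 1-nt substituted UMI (a Hamming-1 neighbor record)
    if errors.umi_substitution_rate > 0:
        hit = np.flatnonzero(rng.random(n_mol) < errors.umi_substitution_rate)
        if len(hit):
            n_err = 1 + rng.binomial(np.maximum(reads_main[hit] - 1, 0), 0.5)
            mut_umi = []
            for i in hit:
                u = emit_umi[i]
                pos = int(rng.integers(UMI_LENGTH))
                alt = "ACGT".replace(u[pos], "")[int(rng.integers(3))]
                mut_umi.append(u[:pos] + alt + u[pos + 1 :])
            rows_bc.append(emit_bc[hit])
            rows_umi.append(np.array(mut_umi, dtype=object))
            rows_gene.append(genes_arr[gene_idx[hit]])
            rows_reads.append(n_err)
            reads_main = reads_main.copy()
            reads_main[hit] -= n_err

    # barcode substitution: per-read errors; erroneous reads of a molecule
    # share one random Hamming-1 neighbor barcode
    if errors.barcode_substitution_rate > 0:
        n_err = rng.binomial(reads_main, errors.barcode_substitution_rate)
        hit = np.flatnonzero(n_err > 0)
        if len(hit):
            mut_bc = []
            for i in hit:
                b = emit_bc[i]
                pos = int(rng.integers(len(b)))
                alt = "ACGT".replace(b[pos], "")[int(rng.integers(3))]
                mut_bc.append(b[:pos] + alt + b[pos + 1 :])
            rows_bc.append(np.array(mut_bc, dtype=object))
            rows_umi.append(emit_umi[hit])
            rows_gene.append(genes_arr[gene_idx[hit]])
            rows_reads.append(n_err[hit])
            reads_main = reads_main.copy()
            reads_main[hit] -= n_err[hit]

    keep = reads_main > 0
    rows_bc.append(emit_bc[keep])
    rows_umi.append(emit_umi[keep])
    rows_gene.append(genes_arr[gene_idx[keep]])
    rows_reads.append(reads_main[keep])

    table = pd.DataFrame(
        {
            "barcode": np.concatenate(rows_bc),
            "umi": np.concatenate(rows_umi),
            "gene": np.concatenate(rows_gene),
            "reads": np.concatenate(rows_reads),
        }
    )
    table = (
        table.groupby(["barcode", "umi", "gene"], sort=True, as_index=False)["reads"]
        .sum()
    )

    new_truth = dataclasses.replace(
        truth,
        barcode_of=pd.Series(truth_barcodes, index=expr.cells, name="barcode"),
        molecules=molecules,
    )
    return table, new_truth


def apply_ambient_contamination(
    expr: ExpressionMatrix, rate: float, seed: int
) -> ExpressionMatrix:
    """Swap a fraction of each cell's molecules for draws from the pooled
    ambient profile, at the matrix level (molecule count preserved)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate outside [0,1]")
    rng = np.random.default_rng(seed)
    dense = expr.counts.toarray()
    pooled = dense.sum(axis=1).astype(float)
    pooled = pooled / pooled.sum()
    out = dense.copy()
    for j in range(dense.shape[1]):
        total = int(dense[:, j].sum())
        if total == 0:
            continue
        n_swap = rng.binomial(total, rate)
        if n_swap == 0:
            continue
        removed = rng.multivariate_hypergeometric(dense[:, j].astype(int), n_swap)
        out[:, j] = dense[:, j] - removed + rng.multinomial(n_swap, pooled)
    return ExpressionMatrix(sp.csr_matrix(out), expr.genes, expr.cells)


# --------------------------------------------------------------------------
# bulk WGS and reference-database simulation
# --------------------------------------------------------------------------

def simulate_wgs_counts(
    genome: GenomeModel,
    copy_number: Mapping[str, int],
    total_reads: int,
    seed: int,
    chromosome_lengths: Mapping[str, float] | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Multinomial per-chromosome read counts for a tumor and its diploid
    germline, weights proportional to length x copies/2 (germline: x1)."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if any(copy_number.get(c, 2) < 0 for c in AUTOSOMES):
        raise ValueError("negative copy number")
    rng = np.random.default_rng(seed)
    if chromosome_lengths is None:
        gpc = genome.genes_per_chromosome
        lengths = np.array([float(gpc.get(c, 0)) for c in AUTOSOMES])
    else:
        lengths = np.array([float(chromosome_lengths[c]) for c in AUTOSOMES])
    if np.any(lengths <= 0):
        raise ValueError("every autosome needs a positive length")
    tumor_w = lengths * np.array([copy_number.get(c, 2) / 2.0 for c in AUTOSOMES])
    germ_w = lengths.copy()
    tumor = rng.multinomial(total_reads, tumor_w / tumor_w.sum())
    germ = rng.multinomial(total_reads, germ_w / germ_w.sum())
    idx = pd.Index(AUTOSOMES, name="chromosome")
    return pd.Series(tumor, index=idx, name="tumor"), pd.Series(
        germ, index=idx, name="germline"
    )


def simulate_reference_db(
    genome: GenomeModel,
    cell_types: Mapping[str, Mapping[str, float]],
    seed: int,
    base_rates: pd.Series | None = None,
    noise_sd: float = 0.05,
    n_distractors: int = 3,
) -> pd.DataFrame:
    """Genes x cell-types reference expression profiles.

    `cell_types` maps a type name to its marker program (gene -> rate
    multiplier); pass the synthetic populations' programs to obtain
    matching references. Distractor types boost random gene blocks.
    Profiles are depth-normalized to counts-per-thousand scale with mild
    log-normal noise.
    """
    rng = np.random.default_rng(seed)
    if base_rates is None:
        base = rng.lognormal(0.0, 1.0, size=len(genome.genes))
    else:
        base = base_rates.reindex(genome.genes).to_numpy(dtype=float)
    profiles = {}
    for name, program in cell_types.items():
        marker = np.array([program.get(g, 1.0) for g in genome.genes])
        rate = base * marker
        rate = rate * rng.lognormal(0.0, noise_sd, size=len(rate))
        profiles[name] = rate / rate.sum() * 1000.0
    for d in range(n_distractors):
        boost_genes = rng.choice(len(genome.genes), size=15, replace=False)
        marker = np.ones(len(genome.genes))
        marker[boost_genes] = 8.0
        rate = base * marker * rng.lognormal(0.0, noise_sd, size=len(base))
        profiles[f"distractor_{d}"] = rate / rate.sum() * 1000.0
    return pd.DataFrame(profiles, index=pd.Index(genome.genes, name="gene"))


def simulate_genebody_exon_ratios(
    cells: pd.Index, dead_fraction: float, seed: int
) -> tuple[pd.Series, pd.Series]:
    """Per-cell gene-body/exon molecule ratio with a dead-cell subpopulation.

    Healthy cells sit near 1.0; dead/compromised cells retain nuclear
    transcripts and sit near 2.0 (above the 1.5 QC cutoff). Returns the
    ratios and the boolean dead-cell truth.
    """
    rng = np.random.default_rng(seed)
    n = len(cells)
    dead = rng.random(n) < dead_fraction
    ratio = np.where(
        dead, rng.normal(2.0, 0.2, size=n), rng.normal(1.0, 0.12, size=n)
    )
    ratio = np.clip(ratio, 0.05, None)
    return (
        pd.Series(ratio, index=cells, name="genebody_exon_ratio"),
        pd.Series(dead, index=cells, name="is_dead"),
    )


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

def _spread_allocator(genome: GenomeModel, exclude: tuple[str, ...] = ("6", "7", "10")):
    """Dispense disjoint marker gene sets spread round-robin over
    chromosomes, so lineage programs do not masquerade as aneuploidies.
    Chromosomes 7/10 (the planted CNAs) and 6 (HLA) are left out."""
    chroms = [c for c in AUTOSOMES if c not in exclude]
    pools = {
        c: [
            g
            for g in genome.genes
            if genome.chromosome_of[g] == c and not genome.hla_flag.get(g, False)
        ]
        for c in chroms
    }
    state = {"ptr": 0, "next": {c: 0 for c in chroms}}

    def take(size: int) -> list[str]:
        out: list[str] = []
        while len(out) < size:
            c = chroms[state["ptr"] % len(chroms)]
            state["ptr"] += 1
            i = state["next"][c]
            if i < len(pools[c]):
                out.append(pools[c][i])
                state["next"][c] = i + 1
        return out

    return take


def graded_profile(
    genome: GenomeModel, rng: np.random.Generator, sigma: float = 0.5
) -> dict[str, float]:
    """Population-wide graded fold-change field: a log-normal multiplier
    per gene. Distinct cell types differ across most of the transcriptome
    by modest graded fold changes, not only at focal markers; without
    this, within-population cells are statistically exchangeable and the
    k-NN graph degenerates into an unstructured random graph that
    modularity clustering shatters."""
    return {
        g: float(v)
        for g, v in zip(genome.genes, rng.lognormal(0.0, sigma, len(genome.genes)))
    }


def preset_populations(
    kind: str, genome: GenomeModel, profile_sigma: float = 0.5, seed: int = 7
) -> tuple[list[PopulationSpec], dict[str, list[str]]]:
    """Canned tumor compositions.

    "branched": neural-lineage-diverse transformed compartment (astrocyte-,
    OPC-, oligodendrocyte-, neuroblast-like subpopulations, chr7 gain /
    chr10 loss) over a diploid microenvironment. "mesenchymal": two
    lineage-poor transformed subpopulations expressing an immune-like
    program, with heavy myeloid infiltration (the PJ017/PJ032 situation).
    Each population carries a graded transcriptome-wide profile (see
    :func:`graded_profile`) under its focal marker program. Returns the
    population list and the named marker gene sets, including a SOX2-like
    gene expressed across every transformed subpopulation.
    """
    rng = np.random.default_rng(seed)
    take = _spread_allocator(genome)
    sets: dict[str, list[str]] = {
        "SOX2_like": take(1),
        "astro": take(12),
        "opc": take(12),
        "oligo": take(12),
        "neuroblast": take(12),
        "myeloid": take(15),
        "tcell": take(12),
        "endothelial": take(12),
        "pericyte": take(12),
        "oligodendrocyte": take(12),
        "immune_like": take(10),
    }

    def program(on: Sequence[str], boost: float, off: Sequence[str] = ()) -> dict:
        prog = graded_profile(genome, rng, profile_sigma)
        prog.update({g: boost for g in on})
        prog.update({g: 0.02 for g in off})
        return prog

    cna = {"7": 3, "10": 1}
    sox_on = {g: 6.0 for g in sets["SOX2_like"]}
    sox_off = {g: 0.02 for g in sets["SOX2_like"]}
    micro_off = sox_off

    if kind == "branched":
        pops = [
            PopulationSpec("astro_like", 0.20, cna,
                           {**program(sets["astro"], 8.0), **sox_on}, 0.05, True),
            PopulationSpec("opc_like", 0.20, cna,
                           {**program(sets["opc"], 8.0), **sox_on}, 0.40, True),
            PopulationSpec("oligo_like", 0.10, cna,
                           {**program(sets["oligo"], 8.0), **sox_on}, 0.05, True),
            PopulationSpec("neuroblast_like", 0.10, cna,
                           {**program(sets["neuroblast"], 8.0), **sox_on}, 0.05, True),
            PopulationSpec("myeloid", 0.15, {},
                           {**program(sets["myeloid"], 10.0), **micro_off}),
            PopulationSpec("tcell", 0.05, {},
                           {**program(sets["tcell"], 10.0), **micro_off}),
            PopulationSpec("endothelial", 0.08, {},
                           {**program(sets["endothelial"], 10.0), **micro_off}),
            PopulationSpec("pericyte", 0.05, {},
                           {**program(sets["pericyte"], 10.0), **micro_off}),
            PopulationSpec("oligodendrocyte", 0.07, {},
                           {**program(sets["oligodendrocyte"], 10.0), **micro_off}),
        ]
    elif kind == "mesenchymal":
        imm = program(sets["immune_like"], 6.0)
        pops = [
            PopulationSpec("mes_1", 0.25, cna,
                           {**program(sets["astro"], 3.0), **imm, **sox_on}, 0.05, True),
            PopulationSpec("mes_2", 0.20, cna,
                           {**imm, **sox_on}, 0.05, True),
            PopulationSpec("myeloid", 0.45, {},
                           {**program(sets["myeloid"], 10.0), **micro_off}),
            PopulationSpec("tcell", 0.05, {},
                           {**program(sets["tcell"], 10.0), **micro_off}),
            PopulationSpec("endothelial", 0.05, {},
                           {**program(sets["endothelial"], 10.0), **micro_off}),
        ]
    else:
        raise ValueError(f"unknown preset {kind!r} (use 'branched' or 'mesenchymal')")
    return pops, sets


# --------------------------------------------------------------------------
# multi-tumor cohort for the contamination-robust signature
# --------------------------------------------------------------------------

def simulate_immune_cohort(
    genome: GenomeModel,
    seed: int,
    n_cells_per_tumor: int = 200,
    depth: float = 1000.0,
    group_tumors: tuple[str, ...] = ("T1", "T2"),
    other_tumors: tuple[str, ...] = ("T3", "T4"),
    contamination: float = 0.01,
    n_intrinsic: int = 5,
    n_ambient: int = 5,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict[str, list[str]]]:
    """Cohort of tumors with planted tumor-intrinsic and ambient genes.

    Group tumors hold 60% transformed / 40% immune cells; the planted
    "intrinsic" genes are strongly expressed only by the group tumors'
    transformed cells (a true tumor-intrinsic immune-like signature),
    while the planted "ambient" genes are expressed only by the group
    tumors' immune cells and leak into transformed cells solely through
    ambient cross-contamination at the given rate. Other tumors carry
    transformed and immune compartments without either program. All
    tumors share one base expression landscape; contamination is applied
    within each tumor against its own pooled profile.

    Returns the concatenated matrix, a cell_info frame (tumor,
    compartment) suitable for contamination_robust_signature, and the
    planted gene sets {"intrinsic": [...], "ambient": [...]}.
    """
    rng = np.random.default_rng(seed)
    base = pd.Series(
        rng.lognormal(0.0, 1.0, size=len(genome.genes)),
        index=pd.Index(genome.genes, name="gene"),
    )
    take = _spread_allocator(genome)
    intrinsic = take(n_intrinsic)
    ambient = take(n_ambient)
    off = {g: 0.001 for g in intrinsic + ambient}

    mats, infos = [], []
    for t, tumor in enumerate(tuple(group_tumors) + tuple(other_tumors)):
        in_group = tumor in group_tumors
        tr_prog = dict(off)
        imm_prog = dict(off)
        if in_group:
            tr_prog.update({g: 8.0 for g in intrinsic})
            imm_prog.update({g: 40.0 for g in ambient})
            imm_prog.update({g: 0.05 for g in intrinsic})
        pops = [
            PopulationSpec("transformed", 0.6, {"7": 3, "10": 1}, tr_prog,
                           is_transformed=True),
            PopulationSpec("immune", 0.4, {}, imm_prog),
        ]
        expr, truth = simulate_expression(
            genome, pops, n_cells_per_tumor, depth,
            seed=int(rng.integers(2**31)), base_rates=base,
        )
        if contamination > 0:
            expr = apply_ambient_contamination(
                expr, contamination, seed=int(rng.integers(2**31))
            )
        cells = pd.Index([f"{tumor}_{c}" for c in expr.cells], name="cell")
        mats.append(ExpressionMatrix(expr.counts, expr.genes, cells))
        infos.append(pd.DataFrame(
            {
                "tumor": tumor,
                "compartment": np.where(
                    truth.population.to_numpy() == "immune", "immune", "transformed"
                ),
            },
            index=cells,
        ))
    combined = ExpressionMatrix(
        sp.hstack([m.counts for m in mats]).tocsr(),
        mats[0].genes,
        mats[0].cells.append([m.cells for m in mats[1:]]),
    )
    return combined, pd.concat(infos), {"intrinsic": intrinsic, "ambient": ambient}
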