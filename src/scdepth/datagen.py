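"""Synthetic droplet scRNA-seq generator for CD4+ T-cell subtype benchmarks.

The generator emulates the statistical shape of a 10x-style CD4+ T-cell
experiment: a handful of transcriptionally similar subtype populations
distinguished by disjoint blocks of up-regulated marker genes, a small
contaminant population lacking CD4/CD3 lineage transcripts, log-normal
library sizes, gamma-Poisson (negative binomial) UMI counts, mitochondrial
genes for QC, and an unstimulated/stimulated condition pair in which
stimulation broadly boosts a subset of genes (raising genes and UMIs per
cell in the stimulated sample).

Sequencing depth is modelled at the molecule level: each latent cDNA
molecule receives a negative-binomial number of reads whose mean is set by
``mean_reads_per_cell``, and a molecule is *observed* as a UMI only when it
receives at least one read. Observed UMI counts therefore increase with
depth and the UMI/read ratio traces a saturating curve, while the emitted
:class:`~scdepth.containers.ReadMultiplicities` records per-entry read
totals so that read-level thinning can be performed downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, ReadMultiplicities, TruthLabels

__all__ = [
    "SubtypePopulation",
    "GeneratorConfig",
    "generate_dataset",
    "generate_paired_conditions",
    "CANONICAL_MARKERS",
    "LINEAGE_MARKERS",
]

# canonical CD4+ T-cell marker symbols always present on the gene axis
CANONICAL_MARKERS = [
    "CD4", "CD3D", "CD3E", "CD3G", "CCR7", "CCR4", "CCR6",
    "FOXP3", "IL2", "CD69", "CD40LG", "SELL",
]
# lineage markers that define a droplet as a CD4+ T cell
LINEAGE_MARKERS = ["CD4", "CD3D", "CD3E", "CD3G"]

# canonical markers folded into the marker set of a subtype of that name
_SUBTYPE_CANONICAL = {
    "naive": ["CCR7", "SELL"],
    "memory": ["CD40LG"],
    "treg": ["FOXP3"],
    "th17": ["CCR6"],
    "th2": ["CCR4"],
}
# stimulation-response genes folded into the stimulated boost set
_STIM_CANONICAL = ["IL2", "CD69"]

CONTAMINANT_LABEL = "non_cd4"


@dataclass(frozen=True)
class SubtypePopulation:
    """One simulated CD4+ subtype population."""

    name: str
    frequency: float
    n_marker_genes: int = 50
    de_factor: float = 4.0


def _default_subtypes() -> tuple:
    # frequencies echo a naive-dominated resting CD4+ sample
    return (
        SubtypePopulation("naive", 0.42),
        SubtypePopulation("memory", 0.20),
        SubtypePopulation("th17", 0.14),
        SubtypePopulation("cytotoxic", 0.12),
        SubtypePopulation("treg", 0.10),
    )


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic experiment.

    Defaults describe the package's default scenario: 2,000 genes x 3,000
    cells, five subtypes with 50 disjoint markers each at 4-fold
    up-regulation, a 2% CD4-/CD3- contaminant population, ~2,500 UMIs per
    cell and a full sequencing depth of 120,000 mean reads per cell.
    """

    n_genes: int = 2000
    n_cells: int = 3000
    subtypes: tuple = field(default_factory=_default_subtypes)
    contaminant_fraction: float = 0.02
    condition: str = "unstimulated"
    stimulation_gene_boost: float = 3.0
    stimulation_fraction: float = 0.10
    stimulation_suppress: float = 0.4
    stimulation_down_fraction: float = 0.05
    stimulation_libsize_factor: float = 1.3
    libsize_meanlog: float = math.log(2500.0)
    libsize_sdlog: float = 0.35
    mito_fraction: float = 0.01
    mito_expression_fraction: float = 0.05
    count_dispersion: float = 0.4
    marker_expression_band: tuple = (0.0, 0.5)
    mean_reads_per_cell: float = 120_000.0
    reads_per_umi_dispersion: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        freqs = [s.frequency for s in self.subtypes]
        total = sum(freqs) + self.contaminant_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"subtype frequencies + contaminant_fraction must sum to 1, got {total}"
            )
        for s in self.subtypes:
            if s.de_factor < 1:
                raise ValueError(f"de_factor must be >= 1 (subtype {s.name})")
            if not 0 <= s.frequency <= 1:
                raise ValueError(f"frequency outside [0,1] (subtype {s.name})")
        for name in ("contaminant_fraction", "stimulation_fraction",
                     "stimulation_down_fraction", "mito_fraction",
                     "mito_expression_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} outside [0,1]: {v}")
        if self.stimulation_gene_boost < 1:
            raise ValueError("stimulation_gene_boost must be >= 1")
        if self.condition not in ("unstimulated", "stimulated"):
            raise ValueError(f"unknown condition: {self.condition!r}")
        if len({s.name for s in self.subtypes}) != len(self.subtypes):
            raise ValueError("duplicate subtype names")
        total_markers = sum(s.n_marker_genes for s in self.subtypes)
        n_reserved = len(CANONICAL_MARKERS) + int(round(self.n_genes * self.mito_fraction))
        if total_markers > self.n_genes - n_reserved:
            raise ValueError("marker gene demand exceeds available genes")


def _gene_symbols(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    n_mito = int(round(config.n_genes * config.mito_fraction))
    symbols = list(CANONICAL_MARKERS)
    symbols += [f"MT-G{i+1}" for i in range(n_mito)]
    symbols += [f"GENE{i:04d}" for i in range(config.n_genes - len(symbols))]
    symbols = np.array(symbols[: config.n_genes], dtype=object)
    is_mito = np.array([s.startswith("MT-") for s in symbols])
    return symbols, is_mito


def _expression_parameters(config: GeneratorConfig, rng: np.random.Generator):
    """Draw the condition-independent gene-level structure."""
    symbols, is_mito = _gene_symbols(config)
    n = config.n_genes
    weights = rng.gamma(shape=0.4, scale=1.0, size=n)
    sym_idx = {s: i for i, s in enumerate(symbols)}

    # lineage markers get a solidly detectable baseline so that CD4/CD3
    # expressing fractions discriminate real T cells from contaminants
    lineage_w = np.quantile(weights[~is_mito], 0.85)
    for s in LINEAGE_MARKERS:
        weights[sym_idx[s]] = lineage_w

    # relative expression shares: mito genes carry a fixed share of counts
    share = np.zeros(n)
    nonmito_w = weights.copy()
    nonmito_w[is_mito] = 0.0
    share = (1.0 - config.mito_expression_fraction) * nonmito_w / nonmito_w.sum()
    if is_mito.any():
        mito_w = rng.gamma(shape=2.0, scale=1.0, size=int(is_mito.sum()))
        share[is_mito] = config.mito_expression_fraction * mito_w / mito_w.sum()

    # disjoint subtype marker blocks drawn from non-mito, non-lineage genes;
    # subtype-defining transcripts (chemokine receptors, transcription
    # factors) are low-to-moderate abundance, so markers come from a banded
    # expression range rather than the whole distribution
    reserved = set(sym_idx[s] for s in LINEAGE_MARKERS) | set(np.flatnonzero(is_mito))
    candidates = np.array([i for i in range(n) if i not in reserved])
    lo_q, hi_q = config.marker_expression_band
    w = weights[candidates]
    lo, hi = np.quantile(w, lo_q), np.quantile(w, hi_q)
    banded = candidates[(w >= lo) & (w <= hi)]
    outside = candidates[(w < lo) | (w > hi)]
    rng.shuffle(banded)
    rng.shuffle(outside)
    # banded genes first; genes outside the band only as a last resort
    pool = list(banded) + list(outside)
    marker_idx: dict[str, np.ndarray] = {}
    cursor = 0
    for sub in config.subtypes:
        anchors = [
            sym_idx[m]
            for m in _SUBTYPE_CANONICAL.get(sub.name, [])
            if sym_idx[m] in set(pool[cursor:])
        ]
        take = [i for i in pool[cursor:] if i in anchors][: len(anchors)]
        need = sub.n_marker_genes - len(take)
        fillers = [i for i in pool[cursor:] if i not in anchors][:need]
        chosen = np.array(take + fillers, dtype=int)
        marker_idx[sub.name] = chosen
        chosen_set = set(chosen)
        pool = [i for i in pool if i not in chosen_set]
    # stimulation-responsive gene sets (disjoint up/down), excluding markers
    n_up = int(round(config.stimulation_fraction * n))
    n_down = int(round(config.stimulation_down_fraction * n))
    stim_pool = list(pool)
    up = list(stim_pool[:n_up])
    for s in _STIM_CANONICAL:
        if sym_idx[s] not in up:
            up.append(sym_idx[s])
    down = [i for i in stim_pool[n_up:] if i not in up][:n_down]
    return symbols, is_mito, share, marker_idx, np.array(up), np.array(down)


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[CountMatrix, ReadMultiplicities, TruthLabels]:
    """Simulate one sample: UMI counts, read totals and truth labels.

    Fully reproducible from ``config.seed``; two configs differing only in
    ``condition`` share all gene-level structure (markers, stimulation
    sets, expression shares), which is what makes paired
    unstimulated/stimulated samples comparable.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    child_params, child_unstim, child_stim = ss.spawn(3)
    rng_param = np.random.default_rng(child_params)
    rng = np.random.default_rng(
        child_stim if config.condition == "stimulated" else child_unstim
    )

    symbols, is_mito, share, marker_idx, stim_up, stim_down = _expression_parameters(
        config, rng_param
    )
    n_genes, n_cells = config.n_genes, config.n_cells

    # cell assignments
    names = [s.name for s in config.subtypes] + [CONTAMINANT_LABEL]
    probs = [s.frequency for s in config.subtypes] + [config.contaminant_fraction]
    assignment = rng.choice(len(names), size=n_cells, p=np.array(probs) / sum(probs))
    subtype_of_cell = np.array([names[a] for a in assignment], dtype=object)

    libsize = rng.lognormal(config.libsize_meanlog, config.libsize_sdlog, size=n_cells)

    # expected molecule counts: share x libsize with multiplicative factors
    mu = np.outer(share, libsize)
    for sub in config.subtypes:
        cells = assignment == names.index(sub.name)
        if cells.any():
            mu[np.ix_(marker_idx[sub.name], cells)] *= sub.de_factor
    contam = assignment == len(config.subtypes)
    if contam.any():
        lineage_rows = [list(symbols).index(s) for s in LINEAGE_MARKERS]
        mu[np.ix_(lineage_rows, contam)] = 0.0
    if config.condition == "stimulated":
        # TCR stimulation raises transcription globally (more genes and
        # UMIs per cell) on top of the focal up/down response sets
        mu *= config.stimulation_libsize_factor
        mu[stim_up, :] *= config.stimulation_gene_boost
        mu[stim_down, :] *= config.stimulation_suppress

    # gamma-Poisson molecules
    phi = config.count_dispersion
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    molecules = rng.poisson(lam).astype(np.int64)
    del lam, mu

    counts, reads = _sequence_molecules(
        molecules, config.mean_reads_per_cell, config.reads_per_umi_dispersion, rng
    )
    del molecules

    barcodes = np.array([f"CELL{i:05d}-1" for i in range(n_cells)], dtype=object)
    cell_meta = pd.DataFrame(
        {"condition": config.condition}, index=pd.Index(barcodes, name="barcode")
    )
    cm = CountMatrix(counts, symbols, barcodes, cell_meta)
    marker_of = {
        symbols[g]: sub for sub, idx in marker_idx.items() for g in idx
    }
    truth = TruthLabels(
        cells=pd.DataFrame(
            {"subtype": subtype_of_cell, "condition": config.condition},
            index=pd.Index(barcodes, name="barcode"),
        ),
        marker_of=marker_of,
        stim_up=[symbols[g] for g in stim_up],
        stim_down=[symbols[g] for g in stim_down],
    )
    return cm, ReadMultiplicities(reads), truth


def _sequence_molecules(
    molecules: np.ndarray,
    mean_reads_per_cell: float,
    dispersion: float,
    rng: np.random.Generator,
) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Assign reads to latent molecules; observe UMIs with >= 1 read.

    Per-molecule read counts are negative binomial with mean chosen so the
    realized total read count is ``mean_reads_per_cell`` per cell in
    expectation, and shape ``1/dispersion``.
    """
    n_genes, n_cells = molecules.shape
    coo = sp.coo_matrix(molecules)
    m_entry = coo.data
    total_molecules = int(m_entry.sum())
    if total_molecules == 0:
        empty = sp.csr_matrix((n_genes, n_cells), dtype=np.int64)
        return empty, empty.copy()
    r = mean_reads_per_cell * n_cells / total_molecules
    size = 1.0 / dispersion
    entry_of_molecule = np.repeat(np.arange(m_entry.size), m_entry)
    reads_per_molecule = rng.negative_binomial(
        size, size / (size + r), size=total_molecules
    )
    observed = reads_per_molecule > 0
    umi_per_entry = np.bincount(
        entry_of_molecule, weights=observed.astype(float), minlength=m_entry.size
    ).astype(np.int64)
    reads_per_entry = np.bincount(
        entry_of_molecule, weights=reads_per_molecule.astype(float), minlength=m_entry.size
    ).astype(np.int64)
    keep = umi_per_entry > 0
    counts = sp.csr_matrix(
        (umi_per_entry[keep], (coo.row[keep], coo.col[keep])), shape=molecules.shape
    )
    reads = sp.csr_matrix(
        (reads_per_entry[keep], (coo.row[keep], coo.col[keep])), shape=molecules.shape
    )
    return counts, reads


def generate_paired_conditions(
    config: GeneratorConfig,
) -> dict[str, tuple[CountMatrix, ReadMultiplicities, TruthLabels]]:
    """Generate a matched unstimulated/stimulated sample pair.

    Both samples share gene-level structure (drawn from ``config.seed``)
    but have independent cells; barcodes are suffixed per condition so the
    pair can be merged without collisions.
    """
    out = {}
    for condition in ("unstimulated", "stimulated"):
        cm, reads, truth = generate_dataset(replace(config, condition=condition))
        suffix = "U" if condition == "unstimulated" else "S"
        new_bc = np.array([f"{b}-{suffix}" for b in cm.barcodes], dtype=object)
        meta = cm.cell_meta.copy()
        meta.index = pd.Index(new_bc, name="barcode")
        cm = CountMatrix(cm.counts, cm.gene_symbols, new_bc, meta)
        cells = truth.cells.copy()
        cells.index = pd.Index(new_bc, name="barcode")
        truth = TruthLabels(cells, truth.marker_of, truth.stim_up, truth.stim_down)
        out[condition] = (cm, reads, truth)
    return out
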