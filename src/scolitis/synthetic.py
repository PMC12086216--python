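"""Cohort-structured synthetic data with planted ground truth.

Three generators emulate the inputs of the pipeline stages:

* :func:`generate_cell_dataset` — sparse UMI count matrices with planted
  compartment / cell-type marker blocks, planted per-cohort composition
  shifts, and planted mitochondrial content;
* :func:`generate_repertoire` — per-patient TCR contig tables in the 10X
  filtered-contig dialect with planted clonal expansion and cross-cluster
  sharing;
* :func:`generate_histology` — per-image probe-positive counts with DAPI
  totals and planted Poisson rate ratios.

Counts follow a negative-binomial (gamma-Poisson) base with gene-level means
drawn log-normal, the weakest model consistent with over-dispersed UMI data.
Each generator draws from its own RNG stream derived from the master seed by
a fixed offset, so adding one generator call never perturbs another's output.

The defaults encode the study conditions of the motivating cohort design:
three cohorts (``MC``, ``chronic_diarrhea``, ``unaffected``) with 16/13/15
expression patients, 8/6/5 TCR patients and 8/8/9 histology slides, ~2000
cells per patient, an MC-shifted cell-type composition (cytotoxic CD8 Trm and
cycling CD8 up, resting CD8 Trm and plasma cells down), 30% vs 5% clonotype
cross-cluster sharing, and a two-fold probe-positive rate in MC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

COHORTS = ("MC", "chronic_diarrhea", "unaffected")

#: 13 protein-coding genes of the human mitochondrial genome; the "MT-" prefix
#: is what the QC stage keys on.
MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8", "MT-CYB",
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class MarkerBlock:
    """A cell type's marker genes: which compartment it belongs to, the genes
    up-lifted in that type, and the multiplicative mean lift (>= 1)."""

    compartment: str
    genes: tuple[str, ...]
    lift: float = 5.0


# Broad per-compartment expression programs shared by all of a compartment's
# cell types; real compartments differ in hundreds of genes, not only in the
# curated scoring markers, and clustering relies on that broad separation.
COMPARTMENT_PROGRAMS: dict[str, tuple[str, ...]] = {
    "immune": ("PTPRC", "CORO1A", "LCP1", "ARHGDIB", "LAPTM5", "SRGN"),
    "epithelial": ("KRT19", "CLDN4", "CDH1", "PHGR1", "TFF3", "LGALS4"),
    "stromal": ("COL3A1", "DCN", "LUM", "SPARC", "MGP", "IGFBP7"),
}


def _block(compartment: str, genes: tuple[str, ...]) -> MarkerBlock:
    return MarkerBlock(compartment, genes + COMPARTMENT_PROGRAMS[compartment])


DEFAULT_MARKER_BLOCKS: dict[str, MarkerBlock] = {
    "CD8_Trm_GZMhi": _block("immune", ("CD3D", "CD3E", "CD2", "CD52", "ITGAE", "GZMA", "GZMB")),
    "CD8_Trm_GZMlo": _block("immune", ("CD3D", "CD3E", "CD2", "CD52", "ITGAE", "IL7R")),
    "CD8_cycling": _block("immune", ("CD3D", "CD3E", "CD2", "CD52", "MKI67", "PCNA")),
    "CD4_T": _block("immune", ("CD3D", "CD3G", "CD2", "CD52", "CD4", "CTLA4")),
    "B_cell": _block("immune", ("CD79A", "CD79B", "MS4A1", "CD52")),
    "Plasma_IGHA": _block("immune", ("JCHAIN", "IGHA1", "SDC1", "MZB1", "CD79A", "CD79B")),
    "Plasma_IGHG": _block("immune", ("JCHAIN", "IGHG1", "SDC1", "XBP1", "CD79A", "CD79B")),
    "Myeloid": _block("immune", ("CD14", "CD68", "CD83", "CSF1R", "FCER1G", "FCGR3A")),
    "Enterocyte": _block("epithelial", ("EPCAM", "KRT8", "KRT18", "FABP1")),
    "Goblet": _block("epithelial", ("EPCAM", "KRT8", "KRT18", "MUC2")),
    "Fibroblast": _block("stromal", ("COL1A1", "COL1A2", "COL6A1", "COL6A2")),
    "Endothelial": _block("stromal", ("VWF", "PLVAP", "CDH5")),
}

_BASE_COMPOSITION = {
    "CD8_Trm_GZMhi": 0.06, "CD8_Trm_GZMlo": 0.14, "CD8_cycling": 0.02,
    "CD4_T": 0.23, "B_cell": 0.15, "Plasma_IGHA": 0.12, "Plasma_IGHG": 0.03,
    "Myeloid": 0.10, "Enterocyte": 0.08, "Goblet": 0.04,
    "Fibroblast": 0.02, "Endothelial": 0.01,
}
_MC_COMPOSITION = {
    "CD8_Trm_GZMhi": 0.15, "CD8_Trm_GZMlo": 0.08, "CD8_cycling": 0.05,
    "CD4_T": 0.22, "B_cell": 0.13, "Plasma_IGHA": 0.07, "Plasma_IGHG": 0.04,
    "Myeloid": 0.10, "Enterocyte": 0.08, "Goblet": 0.04,
    "Fibroblast": 0.03, "Endothelial": 0.01,
}

DEFAULT_COMPOSITION: dict[str, dict[str, float]] = {
    "MC": dict(_MC_COMPOSITION),
    "chronic_diarrhea": dict(_BASE_COMPOSITION),
    "unaffected": dict(_BASE_COMPOSITION),
}


@dataclass(frozen=True)
class ClonalSpec:
    """Planted TCR repertoire structure.

    ``expansion_geom_p`` parameterizes clonotype sizes as Geometric(p) on
    {1, 2, ...}: p = 1 yields all singletons; smaller p yields broader
    expansion.  ``sharing_prob`` is, per cohort, the probability that an
    expanded clonotype spreads its cells over two distinct cell clusters
    instead of one.
    """

    n_patients: dict[str, int] = field(
        default_factory=lambda: {"MC": 8, "chronic_diarrhea": 6, "unaffected": 5}
    )
    n_clonotypes_per_patient: int = 40
    expansion_geom_p: float = 0.5
    sharing_prob: dict[str, float] = field(
        default_factory=lambda: {"MC": 0.30, "chronic_diarrhea": 0.05, "unaffected": 0.05}
    )
    clusters: tuple[str, ...] = (
        "CD8_Trm_GZMhi", "CD8_Trm_GZMlo", "CD8_cycling", "CD8_GZMKhi", "CD8_naive",
    )
    nonproductive_fraction: float = 0.10
    low_confidence_fraction: float = 0.05
    n_libraries: int = 2


@dataclass(frozen=True)
class HistologySpec:
    """Planted histology rates: probe-positive cells per DAPI cell in the MC
    reference cohort, and per-cohort rate ratios relative to MC."""

    probes: tuple[str, ...] = ("GZMB", "HLA-DRB1", "BATF", "FOXP3")
    base_rate: dict[str, float] = field(
        default_factory=lambda: {"GZMB": 0.02, "HLA-DRB1": 0.05, "BATF": 0.01, "FOXP3": 0.015}
    )
    rate_ratio: dict[str, float] = field(
        default_factory=lambda: {"MC": 1.0, "chronic_diarrhea": 0.5, "unaffected": 0.5}
    )
    n_images: dict[str, int] = field(
        default_factory=lambda: {"MC": 8, "chronic_diarrhea": 8, "unaffected": 9}
    )
    dapi_mean: float = 500.0
    dapi_sigma: float = 0.3  # log-scale spread of DAPI totals
    overdispersion: float = 0.0  # gamma-mixing variance; 0 = pure Poisson


@dataclass(frozen=True)
class SimConfig:
    """Master configuration for all three generators."""

    n_patients_per_cohort: dict[str, int] = field(
        default_factory=lambda: {"MC": 16, "chronic_diarrhea": 13, "unaffected": 15}
    )
    n_cells_per_patient: int = 2000
    n_genes: int = 2000
    marker_block_spec: dict[str, MarkerBlock] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_BLOCKS)
    )
    composition_spec: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_COMPOSITION.items()}
    )
    clonal_spec: ClonalSpec = field(default_factory=ClonalSpec)
    histology_spec: HistologySpec = field(default_factory=HistologySpec)
    mito_fraction_range: tuple[float, float] = (0.01, 0.10)
    marker_base_mean: float = 3.0
    gene_mean_log_mu: float = -2.0
    gene_mean_log_sigma: float = 1.2
    nb_dispersion: float = 10.0  # gamma shape; smaller = more over-dispersed
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_per_patient <= 0 or self.n_genes <= 0:
            raise ConfigError("cell and gene counts must be positive")
        for cohort, n in self.n_patients_per_cohort.items():
            if n <= 0:
                raise ConfigError(f"n_patients_per_cohort[{cohort!r}] must be positive")
        gene_to_compartment: dict[str, str] = {}
        for cell_type, block in self.marker_block_spec.items():
            if block.lift < 1:
                raise ConfigError(f"marker lift for {cell_type!r} must be >= 1")
            for g in block.genes:
                prev = gene_to_compartment.setdefault(g, block.compartment)
                if prev != block.compartment:
                    raise ConfigError(
                        f"marker gene {g!r} assigned to both {prev!r} and {block.compartment!r}"
                    )
        for cohort, props in self.composition_spec.items():
            total = float(sum(props.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"composition_spec for cohort {cohort!r} sums to {total!r}, not 1"
                )
            unknown = set(props) - set(self.marker_block_spec)
            if unknown:
                raise ConfigError(
                    f"composition_spec for cohort {cohort!r} names unknown cell types {sorted(unknown)}"
                )
        for cohort, p in self.clonal_spec.sharing_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"sharing probability for cohort {cohort!r} outside [0, 1]")
        if not 0.0 < self.clonal_spec.expansion_geom_p <= 1.0:
            raise ConfigError("expansion_geom_p must be in (0, 1]")
        for probe, rate in self.histology_spec.base_rate.items():
            if rate <= 0:
                raise ConfigError(f"histology base rate for probe {probe!r} must be positive")
        for cohort, rr in self.histology_spec.rate_ratio.items():
            if rr <= 0:
                raise ConfigError(f"histology rate ratio for cohort {cohort!r} must be positive")
        lo, hi = self.mito_fraction_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ConfigError("mito_fraction_range must satisfy 0 <= lo <= hi < 1")

    def with_updates(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Planted ground truth (and retained raw input tables) for one generator run.

    ``contig_tables`` holds the exact per-patient filtered-contig tables the
    repertoire generator emitted, so downstream tests can round-trip parsing
    without regenerating randomness.
    """

    cells: pd.DataFrame | None = None
    clonotypes: pd.DataFrame | None = None
    cell_clusters: pd.Series | None = None
    contig_tables: dict[str, pd.DataFrame] | None = None
    histology_log_rr: pd.DataFrame | None = None
    config: SimConfig | None = None


def _patient_ids(config: SimConfig, spec_counts: dict[str, int]) -> list[tuple[str, str]]:
    short = {"MC": "MC", "chronic_diarrhea": "CD", "unaffected": "UA"}
    out = []
    for cohort in COHORTS:
        if cohort not in spec_counts:
            continue
        for i in range(spec_counts[cohort]):
            out.append((f"{short.get(cohort, cohort)}{i + 1:02d}", cohort))
    return out


def _gene_universe(config: SimConfig) -> list[str]:
    markers: list[str] = []
    for block in config.marker_block_spec.values():
        for g in block.genes:
            if g not in markers:
                markers.append(g)
    genes = markers + list(MITO_GENES)
    n_fill = config.n_genes - len(genes)
    if n_fill < 0:
        raise ConfigError(
            f"n_genes={config.n_genes} too small for {len(genes)} marker + mitochondrial genes"
        )
    genes += [f"G{i:05d}" for i in range(n_fill)]
    return genes


def generate_cell_dataset(config: SimConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Draw a sparse UMI matrix with planted cell types and mito content.

    Returns an AnnData (cells x genes, CSR integer counts) whose ``obs``
    carries patient / cohort / platform columns, plus the truth table with the
    planted cell-type, compartment and mitochondrial-fraction labels.
    Identical (config, seed) yields byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    genes = _gene_universe(config)
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    mito_idx = np.array([gene_index[g] for g in MITO_GENES])

    base_means = rng.lognormal(config.gene_mean_log_mu, config.gene_mean_log_sigma, n_genes)
    # Fixed, comparable baseline for marker genes so a lift of L means an
    # L-fold change regardless of the lognormal draw.
    for block in config.marker_block_spec.values():
        for g in block.genes:
            base_means[gene_index[g]] = config.marker_base_mean
    base_means[mito_idx] = 0.0  # mitochondrial counts are planted separately

    patients = _patient_ids(config, config.n_patients_per_cohort)
    theta = config.nb_dispersion
    lo, hi = config.mito_fraction_range

    blocks_rows = []
    barcodes: list[str] = []
    meta_rows = []
    for patient, cohort in patients:
        props = config.composition_spec[cohort]
        types = list(props)
        counts_per_type = rng.multinomial(config.n_cells_per_patient, [props[t] for t in types])
        platform = "tenx" if rng.random() < 0.5 else "indrops"
        for cell_type, n_cells in zip(types, counts_per_type):
            if n_cells == 0:
                continue
            block = config.marker_block_spec[cell_type]
            means = base_means.copy()
            for g in block.genes:
                means[gene_index[g]] = config.marker_base_mean * block.lift
            lam = rng.gamma(theta, means / theta, size=(n_cells, n_genes))
            counts = rng.poisson(lam).astype(np.int64)
            # Plant mitochondrial content: target fraction f per cell means
            # mito counts ~ Poisson(f/(1-f) * nuclear_total).
            f = rng.uniform(lo, hi, size=n_cells)
            nuclear_total = counts.sum(axis=1)
            mito_total = rng.poisson(f / (1.0 - f) * nuclear_total)
            for j in range(n_cells):
                counts[j, mito_idx] = rng.multinomial(
                    mito_total[j], np.full(len(mito_idx), 1.0 / len(mito_idx))
                )
            blocks_rows.append(sp.csr_matrix(counts))
            start = len(barcodes)
            for j in range(n_cells):
                barcodes.append(f"{patient}_CELL{start + j:05d}")
            for j in range(n_cells):
                meta_rows.append(
                    (patient, cohort, platform, cell_type, block.compartment, f[j])
                )

    X = sp.vstack(blocks_rows, format="csr")
    obs = pd.DataFrame(
        meta_rows,
        columns=["patient", "cohort", "platform", "cell_type", "compartment", "mito_target"],
        index=barcodes,
    )
    adata = ad.AnnData(X=X, obs=obs[["patient", "cohort", "platform", "cell_type"]].copy())
    adata.var_names = genes
    truth = SyntheticTruth(cells=obs.copy(), config=config)
    return adata, truth


def _random_cdr3(rng: np.random.Generator, seen: set[str]) -> str:
    while True:
        n = int(rng.integers(6, 19))
        body = "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, n))
        cdr3 = f"C{body}F"
        if cdr3 not in seen:
            seen.add(cdr3)
            return cdr3


def _cdr3_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(NUCLEOTIDES[k] for k in rng.integers(0, 4, 3 * length))


def generate_repertoire(config: SimConfig):
    """Plant per-patient clonotype tables in the 10X filtered-contig dialect.

    Each clonotype carries one TRA and one TRB CDR3 (globally unique by
    construction); expanded clonotypes (>= 2 cells) spread over two distinct
    clusters with the cohort's sharing probability.  A configurable fraction
    of extra non-productive and low-confidence contigs exercises filtering.
    Patient cells are split over ``n_libraries`` libraries with per-library
    ``raw_clonotype_id`` numbering, so downstream merging is non-trivial.

    Returns ``(repertoires, truth)`` where ``repertoires`` are the planted
    :class:`scolitis.tcr.Repertoire` objects and ``truth`` carries the contig
    tables plus the per-clonotype expansion / sharing flags.
    """
    from .tcr import Repertoire  # local import to avoid a cycle

    config.validate()
    spec = config.clonal_spec
    rng = np.random.default_rng([config.seed, 1])
    seen_cdr3: set[str] = set()

    repertoires: list[Repertoire] = []
    truth_rows = []
    contig_tables: dict[str, pd.DataFrame] = {}
    cluster_records: dict[str, str] = {}

    for patient, cohort in _patient_ids(config, spec.n_patients):
        share_p = spec.sharing_prob[cohort]
        clonotypes: dict[str, tuple[frozenset, set]] = {}
        rows = []
        cell_no = 0
        lib_of_barcode: dict[str, int] = {}
        for k in range(spec.n_clonotypes_per_patient):
            size = int(rng.geometric(spec.expansion_geom_p))
            cdr3_a = _random_cdr3(rng, seen_cdr3)
            cdr3_b = _random_cdr3(rng, seen_cdr3)
            home = spec.clusters[int(rng.integers(len(spec.clusters)))]
            shared = bool(size >= 2 and rng.random() < share_p)
            if shared:
                other_choices = [c for c in spec.clusters if c != home]
                other = other_choices[int(rng.integers(len(other_choices)))]
                assignment = [home, other] + [
                    (home, other)[int(rng.integers(2))] for _ in range(size - 2)
                ]
            else:
                assignment = [home] * size
            member_barcodes = set()
            for cluster in assignment:
                barcode = f"{patient}_TCR{cell_no:05d}-1"
                cell_no += 1
                member_barcodes.add(barcode)
                cluster_records[barcode] = cluster
                lib_of_barcode[barcode] = cell_no % max(spec.n_libraries, 1)
                for chain, cdr3 in (("TRA", cdr3_a), ("TRB", cdr3_b)):
                    rows.append(
                        {
                            "barcode": barcode,
                            "is_cell": "true",
                            "high_confidence": "true",
                            "chain": chain,
                            "v_gene": f"{chain}V{int(rng.integers(1, 30))}",
                            "j_gene": f"{chain}J{int(rng.integers(1, 10))}",
                            "cdr3": cdr3,
                            "cdr3_nt": _cdr3_nt(rng, len(cdr3)),
                            "productive": "true",
                            "raw_clonotype_id": "",  # assigned per library below
                        }
                    )
                if rng.random() < spec.nonproductive_fraction:
                    junk = _random_cdr3(rng, seen_cdr3)
                    rows.append(
                        {
                            "barcode": barcode,
                            "is_cell": "true",
                            "high_confidence": "true",
                            "chain": "TRB",
                            "v_gene": f"TRBV{int(rng.integers(1, 30))}",
                            "j_gene": f"TRBJ{int(rng.integers(1, 10))}",
                            "cdr3": junk,
                            "cdr3_nt": _cdr3_nt(rng, len(junk)),
                            "productive": "false",
                            "raw_clonotype_id": "",
                        }
                    )
                if rng.random() < spec.low_confidence_fraction:
                    junk = _random_cdr3(rng, seen_cdr3)
                    rows.append(
                        {
                            "barcode": barcode,
                            "is_cell": "true",
                            "high_confidence": "false",
                            "chain": "TRA",
                            "v_gene": f"TRAV{int(rng.integers(1, 30))}",
                            "j_gene": f"TRAJ{int(rng.integers(1, 10))}",
                            "cdr3": junk,
                            "cdr3_nt": _cdr3_nt(rng, len(junk)),
                            "productive": "true",
                            "raw_clonotype_id": "",
                        }
                    )
            cid = f"{patient}_CT{k:03d}"
            clonotypes[cid] = (frozenset({cdr3_a, cdr3_b}), member_barcodes)
            truth_rows.append(
                {
                    "patient": patient,
                    "cohort": cohort,
                    "clonotype_id": cid,
                    "n_cells": size,
                    "expanded": size >= 2,
                    "shared": shared,
                    "clusters": ";".join(sorted(set(assignment))),
                }
            )
        table = pd.DataFrame(rows)
        # per-library clonotype numbering in order of appearance, as cellranger does
        lib_ids = table["barcode"].map(lib_of_barcode)
        raw_ids = []
        counters: dict[tuple, str] = {}
        next_id: dict[int, int] = {}
        for bc, lib in zip(table["barcode"], lib_ids):
            key = (lib, bc)
            if key not in counters:
                n = next_id.get(lib, 0) + 1
                next_id[lib] = n
                counters[key] = f"clonotype{n}"
            raw_ids.append(counters[key])
        table["raw_clonotype_id"] = raw_ids
        table["library"] = lib_ids.map(lambda i: f"{patient}_lib{i}")
        contig_tables[patient] = table
        cell_clusters = {
            bc: cluster for bc, cluster in cluster_records.items() if bc.startswith(patient + "_")
        }
        repertoires.append(
            Repertoire(
                patient=patient,
                cohort=cohort,
                clonotypes={cid: (cdr3s, set(bcs)) for cid, (cdr3s, bcs) in clonotypes.items()},
                cell_clusters=cell_clusters,
            )
        )

    truth = SyntheticTruth(
        clonotypes=pd.DataFrame(truth_rows),
        cell_clusters=pd.Series(cluster_records, name="cluster"),
        contig_tables=contig_tables,
        config=config,
    )
    return repertoires, truth


def generate_histology(config: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw per-image probe-positive counts ~ Poisson(rate x DAPI total).

    ``overdispersion`` > 0 gamma-mixes the Poisson rate (variance of the
    multiplicative gamma factor), producing quasi-Poisson-style data.  Truth
    stores the per-cohort log rate ratios relative to the MC reference.
    """
    config.validate()
    spec = config.histology_spec
    rng = np.random.default_rng([config.seed, 2])

    rows = []
    for cohort in COHORTS:
        if cohort not in spec.n_images:
            continue
        rr = spec.rate_ratio[cohort]
        short = {"MC": "MC", "chronic_diarrhea": "CD", "unaffected": "UA"}[cohort]
        for i in range(spec.n_images[cohort]):
            patient = f"{short}_H{i + 1:02d}"
            image = f"{patient}_img"
            dapi = max(20, int(round(rng.lognormal(np.log(spec.dapi_mean), spec.dapi_sigma))))
            for probe in spec.probes:
                mu = spec.base_rate[probe] * rr * dapi
                if spec.overdispersion > 0:
                    v = spec.overdispersion
                    mu = mu * rng.gamma(1.0 / v, v)
                count = int(rng.poisson(mu))
                rows.append(
                    {
                        "image_id": f"{image}_{probe}",
                        "patient": patient,
                        "cohort": cohort,
                        "probe": probe,
                        "compartment": "lamina_propria",
                        "count": count,
                        "dapi_total": dapi,
                    }
                )
    counts = pd.DataFrame(rows)
    log_rr = pd.DataFrame(
        [
            {"probe": probe, "cohort": cohort, "log_rr": float(np.log(spec.rate_ratio[cohort]))}
            for probe in spec.probes
            for cohort in spec.n_images
        ]
    )
    truth = SyntheticTruth(histology_log_rr=log_rr, config=config)
    return counts, truth
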