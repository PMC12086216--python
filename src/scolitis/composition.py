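"""Per-patient cell-type proportions, cohort enrichment stacks, and the
IgG/IgA plasma-cell ratio.

Proportions are computed under a configurable denominator: all cells of the
table (``all_immune``, for tables already restricted to immune cells), the
cell's parent lineage (``parent_lineage``, e.g. all CD8 T cells), cycling
cells only (``cycling_only``), or an explicit ``custom`` set of cell types.
Patients with an empty denominator are emitted with a missing proportion and
flagged, never silently dropped.

The Bayesian compositional model used for significance calls in the
motivating study (scCODA) is not re-implemented; :func:`sccoda_count_table`
emits the patients x cell-types count layout that package expects, so it can
be run externally and its significance annotations joined back on.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DENOMINATOR_SCOPES = ("all_immune", "parent_lineage", "cycling_only", "custom")


def _as_metadata(metadata) -> pd.DataFrame:
    if hasattr(metadata, "obs"):
        metadata = metadata.obs
    df = pd.DataFrame(metadata)
    for col in ("patient", "cohort"):
        if col not in df.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    return df


def per_patient_proportions(
    metadata,
    cell_type_column: str = "cell_type",
    denominator_scope: str = "all_immune",
    lineage_column: str | None = None,
    cycling_types: set[str] | None = None,
    custom_types: set[str] | None = None,
) -> pd.DataFrame:
    """Tidy per-(patient, cell type) counts and proportions.

    Returns one row per patient x cell type with columns ``patient``,
    ``cohort``, ``cell_type``, ``n``, ``denominator``, ``proportion`` and a
    boolean ``empty_denominator`` flag.  For ``parent_lineage`` the
    denominator is the patient's cells of the same lineage (``lineage_column``
    required); for ``cycling_only`` / ``custom`` the table is restricted to
    the cycling / custom cell types and the denominator is the patient's
    total over that restricted set.
    """
    df = _as_metadata(metadata)
    if cell_type_column not in df.columns:
        raise ValueError(f"metadata lacks cell-type column {cell_type_column!r}")
    if denominator_scope not in DENOMINATOR_SCOPES:
        raise ValueError(
            f"unknown denominator_scope {denominator_scope!r}; expected one of {DENOMINATOR_SCOPES}"
        )

    df = df[["patient", "cohort", cell_type_column] + (
        [lineage_column] if lineage_column and lineage_column in df.columns else []
    )].rename(columns={cell_type_column: "cell_type"})

    if denominator_scope == "cycling_only":
        if cycling_types is None:
            cycling_types = {t for t in df["cell_type"].unique() if "cycling" in str(t).lower()}
        df = df[df["cell_type"].isin(cycling_types)]
        types = sorted(cycling_types)
    elif denominator_scope == "custom":
        if not custom_types:
            raise ValueError("custom denominator_scope requires custom_types")
        df = df[df["cell_type"].isin(custom_types)]
        types = sorted(custom_types)
    else:
        types = sorted(df["cell_type"].unique())

    patients = df[["patient", "cohort"]].drop_duplicates()
    if denominator_scope == "parent_lineage":
        if not lineage_column:
            raise ValueError("parent_lineage denominator_scope requires lineage_column")
        group_cols = ["patient", "cohort", lineage_column]
        denom = df.groupby(group_cols, observed=True).size().rename("denominator")
        counts = (
            df.groupby(group_cols + ["cell_type"], observed=True).size().rename("n").reset_index()
        )
        out = counts.merge(denom.reset_index(), on=group_cols)
        out["proportion"] = out["n"] / out["denominator"]
        out["empty_denominator"] = False
        return out.rename(columns={lineage_column: "lineage"})

    counts = (
        df.groupby(["patient", "cell_type"], observed=True).size().rename("n").reset_index()
    )
    grid = patients.merge(pd.DataFrame({"cell_type": types}), how="cross")
    out = grid.merge(counts, on=["patient", "cell_type"], how="left").fillna({"n": 0})
    out["n"] = out["n"].astype(int)
    denom = out.groupby("patient")["n"].transform("sum")
    out["denominator"] = denom.astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["proportion"] = np.where(denom > 0, out["n"] / denom.replace(0, np.nan), np.nan)
    out["empty_denominator"] = out["denominator"] == 0
    n_empty = out.loc[out["empty_denominator"], "patient"].nunique()
    if n_empty:
        logger.info("%d patients with no cells in the %s denominator", n_empty, denominator_scope)
    return out


def enrichment_stack(proportions: pd.DataFrame) -> pd.DataFrame:
    """Per cell type, the share of its pooled cells contributed by each cohort.

    Returns one row per (cell_type, cohort, patient) with the cohort's share
    of the cell type (``cohort_share``, summing to 1 over cohorts within a
    cell type) and the patient's fractional contribution to the cohort's
    cells of the type (``patient_contribution``, summing to 1 over patients
    within cohort x cell type) — the stacked-column layout with per-patient
    transparency bands.
    """
    if proportions.empty:
        raise ValueError("empty proportion table")
    df = proportions[proportions["n"] > 0][["patient", "cohort", "cell_type", "n"]].copy()
    totals = df.groupby("cell_type")["n"].transform("sum")
    cohort_totals = df.groupby(["cell_type", "cohort"])["n"].transform("sum")
    df["cohort_share"] = cohort_totals / totals
    df["patient_contribution"] = df["n"] / cohort_totals
    return df.reset_index(drop=True)


def igg_iga_ratio(metadata, isotype_column: str = "isotype") -> pd.DataFrame:
    """Per-patient ratio of IGHG-isotype to IGHA-isotype plasma cells.

    Isotype labels are consumed as given (IGHG / IGHA / other); a patient
    with IGHG cells but zero IGHA cells has an undefined ratio and is emitted
    with a missing value and ``undefined_ratio=True`` rather than a
    pseudocount — the ratio feeds plots, not models.
    """
    df = _as_metadata(metadata)
    if isotype_column not in df.columns:
        raise ValueError(f"metadata lacks isotype column {isotype_column!r}")
    counts = (
        df.groupby(["patient", "cohort", isotype_column], observed=True)
        .size()
        .unstack(isotype_column, fill_value=0)
        .reset_index()
    )
    ighg = counts.get("IGHG", pd.Series(0, index=counts.index))
    igha = counts.get("IGHA", pd.Series(0, index=counts.index))
    out = counts[["patient", "cohort"]].copy()
    out["n_ighg"] = np.asarray(ighg, dtype=int)
    out["n_igha"] = np.asarray(igha, dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(out["n_igha"] > 0, out["n_ighg"] / out["n_igha"].replace(0, np.nan), np.nan)
    out["ratio"] = ratio
    out["undefined_ratio"] = (out["n_igha"] == 0) & (out["n_ighg"] > 0)
    return out


def sccoda_count_table(metadata, cell_type_column: str = "cell_type") -> pd.DataFrame:
    """Patients x cell-types count table in the layout scCODA expects.

    Rows are patients (with the cohort kept as a covariate column), columns
    are cell types, entries are raw cell counts.
    """
    df = _as_metadata(metadata)
    if cell_type_column not in df.columns:
        raise ValueError(f"metadata lacks cell-type column {cell_type_column!r}")
    table = (
        df.groupby(["patient", "cohort", cell_type_column], observed=True)
        .size()
        .unstack(cell_type_column, fill_value=0)
        .reset_index()
    )
    table.columns.name = None
    return table
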