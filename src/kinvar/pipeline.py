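"""Grid experiments: transform K or K⁻¹ over w/alpha/beta and record responses.

``run_K_grid`` transforms the relationship matrix itself and records, per
cell, the element distribution of the transformed matrix's inverse and the
REML heritability.  ``run_Kinv_grid`` transforms the inverse and records the
cell's own REML heritability plus the correlation and regression slope of
its breeding values against the baseline cell (w=1, alpha=0, beta=0) —
predicted with the baseline heritability, as in routine evaluations where
variance components are not re-estimated, and additionally with each cell's
own heritability to expose the scaling invariance.

Singular or non-positive-definite cells are reported rows with condition
diagnostics, not failures; only a broken baseline aborts a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    PhenotypeTable,
    VarianceComponents,
    build_mme,
    reml_estimate,
    solve_mme,
)
from .relmat import RelationshipMatrix, SingularMatrixError, invert_matrix
from .summaries import ebv_compare, element_summary
from .transform import TransformSpec, condition_report, paper_grid, transform_matrix

__all__ = ["ExperimentConfig", "run_K_grid", "run_Kinv_grid", "pivot_metric"]


@dataclass
class ExperimentConfig:
    """File-level description of a grid experiment (used by the CLI layer)."""

    matrix_kind: str = "A"
    pedigree: str | None = None
    genotypes: str | None = None
    phenotypes: str | None = None
    matrix: str | None = None
    grid_w: tuple[float, ...] = (0.9, 1.0, 1.1)
    grid_alpha: tuple[float, ...] = (-0.05, 0.0, 0.05)
    grid_beta: tuple[float, ...] = (-0.05, 0.0, 0.05)
    band: tuple[float, float] = (-0.02, 0.02)
    blend_weight: float = 0.95
    maf: float = 0.02
    outdir: str = "results"
    seed: int = 0

    def specs(self) -> list[TransformSpec]:
        specs = [
            TransformSpec(w, a, b)
            for w in self.grid_w
            for a in self.grid_alpha
            for b in self.grid_beta
        ]
        if TransformSpec(1.0, 0.0, 0.0) not in specs:
            raise ValueError("the baseline spec (w=1, alpha=0, beta=0) must be in the grid")
        return specs


def _cell(spec: TransformSpec) -> dict:
    return {"w": spec.w, "alpha": spec.alpha, "beta": spec.beta}


def run_K_grid(
    K: RelationshipMatrix,
    phen: PhenotypeTable,
    grid: Sequence[TransformSpec] | None = None,
    band: tuple[float, float] = (-0.02, 0.02),
) -> pd.DataFrame:
    """Transform K per grid cell; summarize (K*)⁻¹ and re-estimate h²."""
    specs = list(grid) if grid is not None else paper_grid(K.kind)
    rows = []
    baseline_ok = False
    for spec in specs:
        Kstar = transform_matrix(K, spec)
        row = {"kind": K.kind, **_cell(spec)}
        cond = condition_report(Kstar)
        row.update(
            min_eigenvalue=cond.smallest_eigenvalue,
            positive_definite=cond.positive_definite,
        )
        if cond.positive_definite:
            inv = invert_matrix(Kstar)
            summ = element_summary(inv, band=band)
            row.update(
                mu_diag_inv=summ.mu_diag,
                sd_diag_inv=summ.sd_diag,
                mu_offdiag_inv=summ.mu_offdiag,
                sd_offdiag_inv=summ.sd_offdiag,
                D_inv=summ.D,
                band_fraction_inv=summ.band_fraction,
            )
            try:
                vc = reml_estimate(Kstar, phen)
                row.update(h2=vc.h2, sigma2_g=vc.sigma2_g, sigma2_e=vc.sigma2_e)
                if spec.is_identity:
                    baseline_ok = True
            except (SingularMatrixError, ValueError) as e:
                row["note"] = f"REML failed: {e}"
        else:
            row["note"] = "transformed K not positive definite"
        rows.append(row)
    if not baseline_ok and any(s.is_identity for s in specs):
        raise SingularMatrixError("baseline cell (w=1, alpha=0, beta=0) failed")
    return pd.DataFrame(rows)


def run_Kinv_grid(
    K_inv: RelationshipMatrix,
    phen: PhenotypeTable,
    grid: Sequence[TransformSpec] | None = None,
    baseline_vc: VarianceComponents | None = None,
) -> pd.DataFrame:
    """Transform K⁻¹ per grid cell; record h² and EBV agreement with baseline.

    EBVs per cell are predicted twice: with the baseline heritability (the
    published comparison) and with the cell's own REML heritability (the
    invariance check for pure rescalings).
    """
    specs = list(grid) if grid is not None else paper_grid(K_inv.kind)
    if baseline_vc is None:
        baseline_vc = reml_estimate(invert_matrix(K_inv), phen)
    lam0 = baseline_vc.lam
    ebv0 = solve_mme(build_mme(K_inv, phen, lam0))

    rows = []
    for spec in specs:
        M = transform_matrix(K_inv, spec)
        row = {"kind": K_inv.kind, **_cell(spec), "h2_baseline": baseline_vc.h2}
        cond = condition_report(M)
        row.update(
            min_eigenvalue=cond.smallest_eigenvalue,
            positive_definite=cond.positive_definite,
        )
        lam_own = None
        if cond.positive_definite:
            try:
                vc = reml_estimate(invert_matrix(M), phen)
                row["h2_own"] = vc.h2
                lam_own = vc.lam
            except (SingularMatrixError, ValueError) as e:
                row["note"] = f"REML failed: {e}"
        else:
            row["note"] = "transformed K-inverse not positive definite"
        try:
            ebv = solve_mme(build_mme(M, phen, lam0))
            cmp_base = ebv_compare(ebv0, ebv)
            row.update(pearson_r=cmp_base.pearson_r, slope=cmp_base.slope)
        except (SingularMatrixError, ValueError) as e:
            row.setdefault("note", f"MME failed: {e}")
        if lam_own is not None:
            ebv_own = solve_mme(build_mme(M, phen, lam_own))
            cmp_own = ebv_compare(ebv0, ebv_own)
            row.update(pearson_r_own=cmp_own.pearson_r, slope_own=cmp_own.slope)
        rows.append(row)
    return pd.DataFrame(rows)


def pivot_metric(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Pivot a long grid table into the (w, alpha) × beta layout of a report."""
    return table.pivot_table(
        index=["w", "alpha"], columns="beta", values=metric, dropna=False
    )
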