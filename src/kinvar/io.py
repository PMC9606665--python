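"""Readers and writers for the plain-text interchange formats.

Pedigree and phenotype tables are CSV, genotypes a delimited matrix with an
id column, relationship matrices either dense TSV with an id header
row/column or MatrixMarket coordinate symmetric format (ids carried in
``%ids:`` comment lines); the matrix reader auto-detects the two.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .model import EbvResult, PhenotypeTable, VarianceComponents
from .relmat import GenotypeMatrix, Pedigree, RelationshipMatrix
from .synthetic_data import SimulatedPopulation

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_genotypes",
    "write_genotypes",
    "read_matrix",
    "write_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "write_ebv",
    "read_ebv",
    "write_variance_components",
    "read_variance_components",
    "write_population",
    "load_wheat_export",
]


def read_pedigree(path: str | Path) -> Pedigree:
    """Pedigree CSV with header id,sire,dam; 0 or empty = unknown parent."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = [c.lower() for c in df.columns]
    if cols[:3] != ["id", "sire", "dam"]:
        raise ValueError("pedigree file must have header columns id,sire,dam")
    return Pedigree.from_records(list(df.itertuples(index=False, name=None)))


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    pd.DataFrame(ped.records(), columns=["id", "sire", "dam"]).to_csv(
        path, index=False
    )


def read_genotypes(path: str | Path, coding: str = "dosage") -> GenotypeMatrix:
    """Delimited genotype matrix: first column id, marker names in the header."""
    df = pd.read_csv(path, sep=None, engine="python")
    ids = df.iloc[:, 0].astype(str).tolist()
    markers = list(df.columns[1:])
    dosages = df.iloc[:, 1:].to_numpy(dtype=np.int64)
    return GenotypeMatrix(ids=ids, markers=markers, dosages=dosages, coding=coding)


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(geno.dosages, columns=geno.markers)
    df.insert(0, "id", geno.ids)
    df.to_csv(path, sep="\t", index=False)


def write_matrix(
    K: RelationshipMatrix, path: str | Path, format: str = "tsv"
) -> None:
    """Write dense TSV (id header row/column) or MatrixMarket symmetric."""
    path = Path(path)
    if format == "tsv":
        pd.DataFrame(K.values, index=K.ids, columns=K.ids).to_csv(path, sep="\t")
    elif format == "mtx":
        tri = scipy.sparse.coo_matrix(np.tril(K.values))
        buf = _io.BytesIO()
        scipy.io.mmwrite(buf, tri, symmetry="symmetric")
        text = buf.getvalue().decode()
        head, _, rest = text.partition("\n")
        id_comments = "".join(
            f"%ids: {' '.join(chunk)}\n"
            for chunk in _chunks(K.ids, 500)
        )
        path.write_text(head + "\n" + f"%kind: {K.kind}\n" + id_comments + rest)
    else:
        raise ValueError("format must be 'tsv' or 'mtx'")


def _chunks(seq: Sequence[str], size: int):
    for i in range(0, len(seq), size):
        yield seq[i : i + size]


def read_matrix(path: str | Path, kind: str = "custom") -> RelationshipMatrix:
    """Auto-detect dense TSV vs MatrixMarket by the %%MatrixMarket banner."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("%%MatrixMarket"):
        ids: list[str] = []
        file_kind = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("%ids:"):
                    ids.extend(line[5:].split())
                elif line.startswith("%kind:"):
                    file_kind = line[6:].strip()
                elif not line.startswith("%"):
                    break
        values = np.asarray(scipy.io.mmread(path).todense(), dtype=float)
        if not ids:
            ids = [str(i + 1) for i in range(values.shape[0])]
        return RelationshipMatrix(ids, values, kind=file_kind or kind)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(
        [str(i) for i in df.index], df.to_numpy(dtype=float), kind=kind
    )


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Phenotype CSV with columns id,value; missing records simply absent."""
    df = pd.read_csv(path)
    return PhenotypeTable(
        ids=df.iloc[:, 0].astype(str).tolist(),
        y=df.iloc[:, 1].to_numpy(dtype=float),
    )


def write_phenotypes(phen: PhenotypeTable, path: str | Path) -> None:
    pd.DataFrame({"id": phen.ids, "value": phen.y}).to_csv(path, index=False)


def write_ebv(result: EbvResult, path: str | Path) -> None:
    pd.DataFrame({"id": result.ids, "ebv": result.ebv}).to_csv(
        path, sep="\t", index=False
    )


def read_ebv(path: str | Path) -> EbvResult:
    df = pd.read_csv(path, sep="\t")
    return EbvResult(
        ids=df["id"].astype(str).tolist(),
        fixed_solutions=np.array([]),
        ebv=df["ebv"].to_numpy(dtype=float),
    )


def write_variance_components(vc: VarianceComponents, path: str | Path) -> None:
    payload = {
        "sigma2_g": float(vc.sigma2_g),
        "sigma2_e": float(vc.sigma2_e),
        "h2": float(vc.h2),
        "lambda": float(vc.lam),
        "n_iter": int(vc.n_iter),
        "converged": bool(vc.converged),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_variance_components(path: str | Path) -> VarianceComponents:
    payload = yaml.safe_load(Path(path).read_text())
    return VarianceComponents(
        sigma2_g=float(payload["sigma2_g"]),
        sigma2_e=float(payload["sigma2_e"]),
        n_iter=int(payload.get("n_iter", 0)),
        converged=bool(payload.get("converged", True)),
    )


def write_population(pop: SimulatedPopulation, outdir: str | Path) -> dict:
    """Write pedigree, masked pedigree, genotypes, phenotypes and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pedigree(pop.pedigree, outdir / "pedigree.csv")
    write_pedigree(pop.masked_pedigree, outdir / "pedigree_masked.csv")
    write_phenotypes(pop.phenotypes, outdir / "phenotypes.csv")
    if pop.genotypes is not None:
        write_genotypes(pop.genotypes, outdir / "genotypes.tsv")
    pd.DataFrame(
        {
            "id": pop.pedigree.ids,
            "generation": pop.generation,
            "sex": np.where(pop.sex == 0, "M", "F"),
            "true_bv": pop.true_breeding_values,
            "inbreeding": pop.inbreeding,
        }
    ).to_csv(outdir / "truth.csv", index=False)
    cfg = pop.config
    manifest = {
        "n_individuals": len(pop.pedigree),
        "n_phenotyped": len(pop.phenotypes),
        "n_genotyped": len(pop.genotyped_ids),
        "n_markers": 0 if pop.genotypes is None else pop.genotypes.n_markers,
        "n_masked_sires": int(
            np.sum((pop.pedigree.sire_idx >= 0) & (pop.masked_pedigree.sire_idx < 0))
        ),
        "n_masked_dams": int(
            np.sum((pop.pedigree.dam_idx >= 0) & (pop.masked_pedigree.dam_idx < 0))
        ),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cfg).items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_wheat_export(directory: str | Path):
    """Load a directory of files exported from the BGLR wheat dataset.

    Expected plain-text exports (written from R): ``A.tsv`` (dense pedigree
    relationship matrix with line names), ``X.tsv`` (0/1 marker matrix, first
    column the line name) and ``y.csv`` (line, phenotype).  Returns
    ``(A, genotypes, phenotypes)``.  The A matrix is taken as given (its
    internal pedigree, including any inbreeding, is not reconstructed).
    """
    directory = Path(directory)
    A = read_matrix(directory / "A.tsv", kind="A")
    geno = read_genotypes(directory / "X.tsv", coding="binary")
    phen = read_phenotypes(directory / "y.csv")
    return A, geno, phen
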