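"""Reading and writing genotype/phenotype tables, VCF conversion and
model serialization.

Tables are delimited text (comma or tab, auto-detected): genotype files
have a header row of marker IDs and a first column of sample IDs;
phenotype files have a sample-ID column followed by named trait
columns.  VCF input is converted to ALT-allele dosage with markers as
columns (records are transposed on import).  Models serialize to a
versioned JSON container.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, PhenotypeVector
from .model import ILSTSVR, ILSTSVRHyperparams, TwinRegressionResults

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = "twingp-model-1"

__all__ = ["read_genotype_table", "write_genotype_table",
           "read_phenotype_table", "write_phenotype_table", "align_samples",
           "vcf_to_dosage", "save_model", "load_model"]


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", index_col=0,
                       dtype=str)


def _to_numeric(df: pd.DataFrame, what: str) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    # locate parse failures: coerced NaN where the original cell was not empty
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric {what} cell at sample {df.index[i]!r}, "
            f"column {df.columns[j]!r}: {df.iat[i, j]!r}")
    return out


def read_genotype_table(path, impute_missing: bool = False) -> GenotypeMatrix:
    """Load a samples x markers dosage table.

    Missing cells are rejected by default; with ``impute_missing`` they
    are replaced by the marker (column) mean.
    """
    df = _read_table(path)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    num = _to_numeric(df, "genotype")
    if num.isna().to_numpy().any():
        if impute_missing:
            num = num.fillna(num.mean(axis=0))
            if num.isna().to_numpy().any():
                j = num.columns[num.isna().any(axis=0)][0]
                raise ValueError(f"marker {j!r} is entirely missing")
        else:
            i, j = np.argwhere(num.isna().to_numpy())[0]
            raise ValueError(
                f"missing genotype at sample {num.index[i]!r}, marker "
                f"{num.columns[j]!r} (pass impute_missing=True to mean-impute)")
    return GenotypeMatrix(num.to_numpy(dtype=float), list(num.index),
                          [str(c) for c in num.columns])


def write_genotype_table(X: GenotypeMatrix, path, sep: str = ","):
    df = pd.DataFrame(X.values, index=X.sample_ids, columns=X.marker_ids)
    df.index.name = "sample"
    df.to_csv(path, sep=sep)


def read_phenotype_table(path, trait: str | None = None) -> PhenotypeVector:
    """Load one trait column; file order is preserved."""
    df = _read_table(path)
    if trait is None:
        trait = str(df.columns[0])
    if trait not in df.columns:
        raise ValueError(
            f"trait {trait!r} not found; available traits: "
            f"{', '.join(map(str, df.columns))}")
    num = _to_numeric(df[[trait]], "phenotype")
    return PhenotypeVector(num[trait].to_numpy(dtype=float), list(df.index),
                           trait)


def write_phenotype_table(Y: PhenotypeVector, path, sep: str = ","):
    df = pd.DataFrame({Y.trait: Y.values}, index=Y.sample_ids)
    df.index.name = "sample"
    df.to_csv(path, sep=sep)


def align_samples(X: GenotypeMatrix, Y: PhenotypeVector):
    """Inner-join genotypes and phenotypes on sample ID.

    Genotype-file order is preserved; dropped samples are logged.
    """
    ypos = {s: i for i, s in enumerate(Y.sample_ids)}
    keep = [i for i, s in enumerate(X.sample_ids) if s in ypos]
    if not keep:
        raise ValueError("no shared sample ids between genotypes and phenotypes")
    dropped_x = X.n_samples - len(keep)
    dropped_y = Y.n_samples - len(keep)
    if dropped_x or dropped_y:
        logger.warning("align_samples dropped %d genotype and %d phenotype "
                       "samples without a match", dropped_x, dropped_y)
    Xa = X.take_samples(keep)
    Ya = Y.take([ypos[X.sample_ids[i]] for i in keep])
    return Xa, Ya


def vcf_to_dosage(path, impute_missing: bool = False) -> GenotypeMatrix:
    """Convert a VCF with GT fields to an ALT-dosage matrix.

    Biallelic sites only; multiallelic records are skipped with a count
    in the log.  Marker IDs come from the ID column, falling back to
    CHROM:POS.  Missing genotypes are marker-mean imputed when
    ``impute_missing`` is set, otherwise rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, ids = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = rec.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        cols.append(dos)
        ids.append(rec.ID if rec.ID not in (None, ".", "")
                   else f"{rec.CHROM}:{rec.POS}")
    if n_multi:
        logger.warning("skipped %d multiallelic records", n_multi)
    if not cols:
        raise ValueError(f"no usable biallelic records in {path}")
    mat = np.column_stack(cols)
    if np.isnan(mat).any():
        if not impute_missing:
            i, j = np.argwhere(np.isnan(mat))[0]
            raise ValueError(
                f"missing genotype for sample {samples[i]!r} at marker "
                f"{ids[j]!r} (pass impute_missing=True)")
        means = np.nanmean(mat, axis=0)
        idx = np.where(np.isnan(mat))
        mat[idx] = means[idx[1]]
    return GenotypeMatrix(mat, samples, ids)


def save_model(results: TwinRegressionResults, path):
    """Serialize a fitted model to a versioned JSON container."""
    hp = results.hyperparams
    train_X = results.model.exog
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "hyperparams": {"C1": hp.C1, "C3": hp.C3, "eps1": hp.eps1,
                        "eps2": hp.eps2, "kernel": hp.kernel,
                        "sigma": hp.sigma},
        "w1": results.w1.tolist(), "b1": results.b1,
        "w2": results.w2.tolist(), "b2": results.b2,
        "alpha1": results.alpha1.tolist(), "alpha2": results.alpha2.tolist(),
        "n_iterations": results.n_iterations,
        "converged": results.converged,
        "n_markers": train_X.n_markers,
        "marker_ids": list(train_X.marker_ids),
    }
    if hp.kernel == "rbf":
        payload["train_X"] = {
            "values": train_X.values.tolist(),
            "sample_ids": list(train_X.sample_ids),
        }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> TwinRegressionResults:
    """Load a model saved by :func:`save_model`; predictions are
    bit-identical to the original's."""
    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as err:
        raise ValueError(f"corrupt or truncated model file {path}") from err
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format {version!r} (expected "
            f"{MODEL_FORMAT_VERSION!r})")
    hp = ILSTSVRHyperparams(**payload["hyperparams"])
    m = payload["n_markers"]
    if hp.kernel == "rbf":
        tx = payload["train_X"]
        X = GenotypeMatrix(np.array(tx["values"], dtype=float),
                           tx["sample_ids"], payload["marker_ids"])
        n = X.n_samples
    else:
        # linear models do not need the training genotypes for prediction;
        # a two-row placeholder keeps the model object well-formed
        n = 2
        X = GenotypeMatrix(np.zeros((n, m)), None, payload["marker_ids"])
    model = ILSTSVR(np.zeros(n), X, hp)
    return TwinRegressionResults(
        model=model,
        w1=np.array(payload["w1"], dtype=float), b1=float(payload["b1"]),
        w2=np.array(payload["w2"], dtype=float), b2=float(payload["b2"]),
        alpha1=np.array(payload["alpha1"], dtype=float),
        alpha2=np.array(payload["alpha2"], dtype=float),
        n_iterations=int(payload["n_iterations"]),
        converged=bool(payload["converged"]),
    )
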