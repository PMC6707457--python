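"""Reading, validating and writing genotype matrices and fit results.

The central container is :class:`GenotypeMatrix`: an ``m x n`` integer
matrix of reference-allele counts with SNPs in rows and individuals in
columns.  Every entry is 0, 1 or 2 (diploid data).  Readers accept
delimited text (whitespace, comma or tab, auto-detected) and bi-allelic
VCF; fit results are written as TSV plus a JSON metadata sidecar.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GenotypeValidationError",
    "read_genotype_matrix",
    "write_fit",
]

_VALID_GENOTYPES = frozenset({0, 1, 2})


class GenotypeValidationError(ValueError):
    """Raised when genotype data violates the {0,1,2} coding contract."""


@dataclass
class GenotypeMatrix:
    """``m x n`` matrix of reference-allele counts (SNPs x individuals).

    Parameters
    ----------
    values
        Integer matrix with every entry in {0, 1, 2}.
    snp_ids
        Optional length-``m`` SNP identifiers.
    sample_ids
        Optional length-``n`` sample identifiers.
    """

    values: np.ndarray
    snp_ids: Sequence[str] | None = None
    sample_ids: Sequence[str] | None = None
    n_monomorphic: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise GenotypeValidationError(
                f"genotype matrix must be 2-dimensional, got shape {values.shape}"
            )
        if values.size == 0:
            raise GenotypeValidationError("genotype matrix must be non-empty")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.rint(values)):
                bad = np.argwhere(~np.isin(values, [0.0, 1.0, 2.0]))
                raise GenotypeValidationError(
                    f"non-integer genotype at (row, column) = {tuple(bad[0])}"
                )
            values = values.astype(np.int8)
        _validate_range(values)
        if values.dtype != np.int8:
            values = values.astype(np.int8)
        self.values = values
        m, n = values.shape
        if self.snp_ids is not None and len(self.snp_ids) != m:
            raise GenotypeValidationError("snp_ids length does not match row count")
        if self.sample_ids is not None and len(self.sample_ids) != n:
            raise GenotypeValidationError("sample_ids length does not match column count")
        if m < n:
            warnings.warn(
                f"genotype matrix has fewer SNPs (m={m}) than individuals (n={n}); "
                "the method is designed for m >> n",
                stacklevel=3,
            )
        # monomorphic rows are retained but counted for the validation report
        row_min = values.min(axis=1)
        row_max = values.max(axis=1)
        self.n_monomorphic = int(np.sum((row_min == row_max) & np.isin(row_min, [0, 2])))

    @property
    def m(self) -> int:
        """Number of SNPs (rows)."""
        return self.values.shape[0]

    @property
    def n(self) -> int:
        """Number of individuals (columns)."""
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _validate_range(values: np.ndarray) -> None:
    bad = (values < 0) | (values > 2)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeValidationError(
            f"genotype {values[i, j]} outside {{0,1,2}} at (row, column) = ({i}, {j})"
        )


def _detect_delimiter(path: Path) -> str | None:
    """Return ',' or '\\t' when the first line uses them, else None (whitespace)."""
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return None


def _read_delimited(path: Path, missing_policy: str) -> GenotypeMatrix:
    sep = _detect_delimiter(path)
    try:
        df = pd.read_csv(
            path,
            sep=sep if sep is not None else r"\s+",
            header=None,
            na_values=["NA", "na", "NaN", "nan", "."],
            comment="#",
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenotypeValidationError(f"could not parse {path}: {exc}") from exc
    values = df.to_numpy(dtype=float)
    missing = np.isnan(values)
    if missing.any():
        if missing_policy == "error":
            i, j = np.argwhere(missing)[0]
            raise GenotypeValidationError(
                f"missing genotype at (row, column) = ({i}, {j}) with policy='error'"
            )
        values = _mean_impute(values, missing)
    non_integer = values != np.rint(values)
    if non_integer.any():
        i, j = np.argwhere(non_integer)[0]
        raise GenotypeValidationError(
            f"non-integer genotype {values[i, j]} at (row, column) = ({i}, {j})"
        )
    return GenotypeMatrix(values.astype(np.int64))


def _mean_impute(values: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Replace missing entries by the SNP (row) mean rounded into {0,1,2}."""
    out = values.copy()
    for i in np.unique(np.argwhere(missing)[:, 0]):
        row = values[i]
        obs = row[~missing[i]]
        if obs.size == 0:
            raise GenotypeValidationError(
                f"row {i} has no observed genotypes; cannot mean-impute"
            )
        fill = float(np.clip(np.rint(obs.mean()), 0, 2))
        out[i, missing[i]] = fill
    return out


def _read_vcf(path: Path, missing_policy: str) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF input requires the cyvcf2 package") from exc

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows: list[np.ndarray] = []
    snp_ids: list[str] = []
    any_missing = False
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise GenotypeValidationError(
                f"multi-allelic site at {variant.CHROM}:{variant.POS}; "
                "split or filter to bi-allelic sites first"
            )
        counts = np.empty(len(sample_ids), dtype=float)
        for j, gt in enumerate(variant.genotypes):
            alleles = gt[:2]
            n_missing = sum(a < 0 for a in alleles)
            if n_missing == 1:
                raise GenotypeValidationError(
                    f"half-called genotype for sample {sample_ids[j]} at "
                    f"{variant.CHROM}:{variant.POS}"
                )
            if n_missing == 2:
                counts[j] = np.nan
                any_missing = True
            else:
                # reference-allele count = 2 - (number of ALT alleles)
                counts[j] = 2 - sum(1 for a in alleles if a == 1)
        rows.append(counts)
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    if not rows:
        raise GenotypeValidationError(f"no variants found in {path}")
    values = np.vstack(rows)
    if any_missing:
        missing = np.isnan(values)
        if missing_policy == "error":
            i, j = np.argwhere(missing)[0]
            raise GenotypeValidationError(
                f"missing genotype at (row, column) = ({i}, {j}) with policy='error'"
            )
        values = _mean_impute(values, missing)
    return GenotypeMatrix(values.astype(np.int64), snp_ids=snp_ids, sample_ids=sample_ids)


def read_genotype_matrix(
    path: str | Path,
    format: Literal["delimited", "vcf"] = "delimited",
    missing_policy: Literal["error", "mean_impute"] = "error",
    transpose: bool = False,
) -> GenotypeMatrix:
    """Read a genotype matrix from delimited text or VCF.

    Parameters
    ----------
    path
        Input file.  Delimited files hold an ``m x n`` numeric matrix
        (SNPs in rows); VCF files must contain only bi-allelic sites with
        diploid GT fields, which are converted to reference-allele counts.
    format
        ``"delimited"`` or ``"vcf"``.
    missing_policy
        ``"error"`` rejects missing entries; ``"mean_impute"`` replaces each
        by its SNP's observed mean rounded to the nearest value in {0,1,2}.
        Imputation is a pragmatic approximation: the admixture model itself
        has no missing-data mechanism.
    transpose
        Transpose after reading, for files stored individuals x SNPs.
        Orientation is never guessed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if missing_policy not in ("error", "mean_impute"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if format == "delimited":
        geno = _read_delimited(path, missing_policy)
    elif format == "vcf":
        geno = _read_vcf(path, missing_policy)
    else:
        raise ValueError(f"unknown format {format!r}")
    if transpose:
        geno = GenotypeMatrix(geno.values.T, snp_ids=geno.sample_ids, sample_ids=geno.snp_ids)
    return geno


def write_genotype_matrix(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as whitespace-delimited integer text (row = SNP)."""
    np.savetxt(path, geno.values, fmt="%d")


def write_fit(fit, out_dir: str | Path, include_F: bool = False) -> dict[str, Path]:
    """Write an admixture fit to ``out_dir`` as TSV files plus a JSON sidecar.

    ``Q.tsv`` holds admixture proportions (d rows x n samples, sample ids as
    header when available), ``P.tsv`` the ancestral allele frequencies
    (m x d).  The large individual-specific frequency matrix ``F.tsv`` is
    written only when ``include_F`` is set.  The sidecar records d, the
    algorithm, tolerance, iteration count and seed so a run can be
    reproduced exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    d, n = fit.Q.shape
    sample_ids = fit.sample_ids if fit.sample_ids is not None else [f"sample{j}" for j in range(n)]
    pop_ids = [f"pop{k}" for k in range(d)]

    paths: dict[str, Path] = {}
    q_df = pd.DataFrame(fit.Q, index=pop_ids, columns=sample_ids)
    paths["Q"] = out_dir / "Q.tsv"
    q_df.to_csv(paths["Q"], sep="\t", float_format="%.17g")

    p_df = pd.DataFrame(fit.P, columns=pop_ids)
    if fit.snp_ids is not None:
        p_df.index = pd.Index(fit.snp_ids)
    paths["P"] = out_dir / "P.tsv"
    p_df.to_csv(paths["P"], sep="\t", float_format="%.17g")

    if include_F:
        paths["F"] = out_dir / "F.tsv"
        np.savetxt(paths["F"], fit.F, fmt="%.17g", delimiter="\t")

    meta = {
        "d": int(d),
        "m": int(fit.P.shape[0]),
        "n": int(n),
        "algorithm": fit.algorithm,
        "tol": fit.tol,
        "max_iter": fit.max_iter,
        "iterations": int(fit.iterations),
        "converged": bool(fit.converged),
        "seed": fit.seed,
        "clamped_fraction": float(fit.clamped_fraction),
    }
    paths["meta"] = out_dir / "fit_meta.json"
    with open(paths["meta"], "w") as fh:
        json.dump(meta, fh, indent=2)
    return paths


def read_matrix_tsv(path: str | Path, index_col: int | None = 0) -> np.ndarray:
    """Read back a TSV written by :func:`write_fit` as a float matrix."""
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    return df.to_numpy(dtype=float)
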