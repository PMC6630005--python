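"""Readers and writers for the on-disk formats of the pleiotropy pipeline.

Formats handled here:

* GWAS summary statistics — tab-delimited with a header naming at least
  ``snp_id``, ``chrom``, ``pos``, ``pvalue`` (optional ``maf``).
* Gene annotation — BED3+name, 0-based half-open intervals.
* Reference panel — either a TSV dosage matrix (rows = SNPs, columns =
  individuals, values 0/1/2, first columns ``snp_id``/``chrom``/``pos``)
  or a minimal biallelic VCF with GT genotypes.
* Expression matrices — TSV, transcripts x samples, log2 scale, with a
  sample -> case|control labels file and an optional alias -> official
  symbol mapping table.

Coordinate conventions: BED intervals are 0-based half-open, SNP positions
are 1-based, so a SNP lies inside a gene iff ``start < pos <= end``.
Chromosome names are normalised by stripping a leading ``chr``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "SnpAssociation",
    "GeneModel",
    "ExpressionDataset",
    "ReferencePanel",
    "AnalysisConfig",
    "FormatError",
    "normalize_chrom",
    "read_gwas_summary",
    "read_gene_annotation",
    "read_reference_panel",
    "read_expression_dataset",
    "load_config",
    "write_table",
    "read_table",
]


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so mixed-dialect inputs join cleanly."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's association record from a GWAS summary-statistics table."""

    snp_id: str
    chrom: str
    pos: int  # 1-based bp
    pvalue: float  # in (0, 1]
    maf: float | None = None  # minor allele frequency, in [0, 0.5]


@dataclass(frozen=True)
class GeneModel:
    """A gene span in BED convention: 0-based start, exclusive end."""

    symbol: str
    chrom: str
    start: int
    end: int

    def contains(self, pos: int, flank_bp: int = 0) -> bool:
        """Whether a 1-based SNP position falls within the (flanked) span."""
        return self.start - flank_bp < pos <= self.end + flank_bp


@dataclass
class ExpressionDataset:
    """A case/control expression matrix on the log2 scale.

    ``gene_symbols`` holds the official human symbol per transcript after
    alias mapping; transcripts whose alias could not be mapped keep an empty
    symbol and are ignored by downstream screens.
    """

    values: np.ndarray  # transcripts x samples
    transcript_ids: list[str]
    gene_symbols: list[str]
    group_labels: list[str]  # "case" | "control" per sample column
    dataset_name: str = ""
    sample_ids: list[str] = field(default_factory=list)

    @property
    def case_columns(self) -> np.ndarray:
        return np.array([g == "case" for g in self.group_labels])

    def values_for(self, transcript_index: int) -> tuple[np.ndarray, np.ndarray]:
        """(case values, control values) for one transcript row."""
        mask = self.case_columns
        row = self.values[transcript_index]
        return row[mask], row[~mask]


@dataclass
class ReferencePanel:
    """Genotype dosages used to estimate LD.

    ``dosages`` is individuals x SNPs with values in {0, 1, 2}; ``snps`` is a
    DataFrame with columns snp_id/chrom/pos in matching column order.
    Monomorphic SNPs are flagged and excluded from correlation computations.
    """

    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError("dosage matrix does not match SNP metadata")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["snp_id"].tolist()

    @property
    def monomorphic(self) -> np.ndarray:
        return self.dosages.std(axis=0) == 0

    @property
    def allele_frequency(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0

    def index_of(self, snp_ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snps["snp_id"])}
        missing = [s for s in snp_ids if s not in lookup]
        if missing:
            raise KeyError(f"SNPs absent from reference panel: {missing[:5]}")
        return np.array([lookup[s] for s in snp_ids], dtype=int)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the whole pipeline.

    Defaults follow the analysis conventions: nominal significance 0.05,
    two phenotypes, LD-proxy threshold r^2 > 0.8 with zero flank around the
    gene span, MAF filter at 0.01, and a 2-fold (|log2FC| > 1) change called
    "large" in the expression stage.
    """

    alpha_nominal: float = 0.05
    n_phenotypes: int = 2
    r2_proxy_threshold: float = 0.8
    flank_bp: int = 0
    maf_min: float = 0.01
    mc_schedule: tuple[int, ...] = (10**3, 10**4, 10**5, 10**6)
    rng_seed: int = 0
    fold_change_log2_cutoff: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha_nominal", "r2_proxy_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        sched = tuple(int(n) for n in self.mc_schedule)
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("mc_schedule must be strictly increasing")
        self.mc_schedule = sched


def load_config(path: str | Path, **overrides) -> AnalysisConfig:
    """Load an AnalysisConfig from a flat key/value YAML file.

    Keyword overrides (e.g. CLI flags) take precedence over file values.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"config {path} is not a flat key/value mapping")
    known = AnalysisConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return AnalysisConfig(**raw)


# ---------------------------------------------------------------------------
# GWAS summary statistics


def read_gwas_summary(path: str | Path, maf_min: float = 0.01) -> list[SnpAssociation]:
    """Read a tab-delimited GWAS summary table.

    Rows with MAF below ``maf_min`` are filtered out; rows with p-values
    outside (0, 1] are rejected and their count reported through the module
    logger. The result is sorted by (chrom, pos).
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    required = {"snp_id", "chrom", "pos", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    dup = df["snp_id"][df["snp_id"].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicate snp_id {dup.iloc[0]!r}")

    bad_p = ~((df["pvalue"] > 0) & (df["pvalue"] <= 1))
    if bad_p.any():
        logger.warning(
            "%s: rejected %d rows with p-values outside (0,1]", path, int(bad_p.sum())
        )
        df = df[~bad_p]
    if "maf" in df.columns:
        low_maf = df["maf"].notna() & (df["maf"] < maf_min)
        if low_maf.any():
            logger.info(
                "%s: filtered %d rows with MAF < %g", path, int(low_maf.sum()), maf_min
            )
            df = df[~low_maf]

    df = df.assign(chrom=df["chrom"].map(normalize_chrom))
    df = df.sort_values(["chrom", "pos"], kind="mergesort")
    has_maf = "maf" in df.columns
    return [
        SnpAssociation(
            snp_id=r.snp_id,
            chrom=r.chrom,
            pos=int(r.pos),
            pvalue=float(r.pvalue),
            maf=(float(r.maf) if has_maf and pd.notna(r.maf) else None),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Gene annotation (BED)


def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Read BED3+name gene annotation (0-based half-open intervals)."""
    genes: list[GeneModel] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected BED3+name, got {len(parts)} fields")
            chrom, start_s, end_s, symbol = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval [{start}, {end}) for {symbol}"
                )
            if symbol in seen:
                raise FormatError(
                    f"{path}:{lineno}: duplicate gene symbol {symbol!r} "
                    f"(first seen at line {seen[symbol]})"
                )
            seen[symbol] = lineno
            genes.append(GeneModel(symbol, normalize_chrom(chrom), start, end))
    return genes


# ---------------------------------------------------------------------------
# Reference panel


def read_reference_panel(path: str | Path) -> ReferencePanel:
    """Read a reference panel from a TSV dosage matrix or a minimal VCF.

    The TSV dialect has header columns ``snp_id``, ``chrom``, ``pos`` followed
    by one column per individual with dosages in {0, 1, 2}. The VCF dialect is
    restricted to biallelic rows with GT genotypes; multi-allelic rows are
    skipped with a warning.
    """
    path = Path(path)
    if path.suffix == ".vcf":
        return _read_panel_vcf(path)
    return _read_panel_tsv(path)


def _read_panel_tsv(path: Path) -> ReferencePanel:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    for col in ("snp_id", "chrom", "pos"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing panel column {col!r}")
    dup = df["snp_id"][df["snp_id"].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicate SNP {dup.iloc[0]!r} in panel")
    sample_cols = [c for c in df.columns if c not in ("snp_id", "chrom", "pos")]
    if not sample_cols:
        raise FormatError(f"{path}: panel has no individual columns")
    dosages = df[sample_cols].to_numpy(dtype=float).T  # individuals x SNPs
    if not np.isin(dosages, (0.0, 1.0, 2.0)).all():
        bad = dosages[~np.isin(dosages, (0.0, 1.0, 2.0))][0]
        raise FormatError(f"{path}: dosage value {bad} outside {{0,1,2}}")
    meta = df[["snp_id", "chrom", "pos"]].assign(chrom=df["chrom"].map(normalize_chrom))
    panel = ReferencePanel(snps=meta, dosages=dosages.astype(np.int8))
    _warn_monomorphic(panel, path)
    return panel


def _read_panel_vcf(path: Path) -> ReferencePanel:
    rows, dosage_rows = [], []
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 10:
                raise FormatError(f"{path}: VCF data row with no genotype columns")
            chrom, pos, vid, _ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if "," in alt:
                n_skipped += 1
                continue
            gts = []
            for sample in parts[9:]:
                gt = sample.split(":")[0].replace("|", "/")
                alleles = gt.split("/")
                if any(a == "." for a in alleles):
                    raise FormatError(f"{path}: missing genotype for {vid}")
                gts.append(sum(int(a) for a in alleles))
            rows.append((vid, normalize_chrom(chrom), int(pos)))
            dosage_rows.append(gts)
    if n_skipped:
        logger.warning("%s: skipped %d multi-allelic VCF rows", path, n_skipped)
    meta = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])
    dup = meta["snp_id"][meta["snp_id"].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicate SNP {dup.iloc[0]!r} in panel")
    dosages = np.array(dosage_rows, dtype=np.int8).T
    if dosages.size and not np.isin(dosages, (0, 1, 2)).all():
        raise FormatError(f"{path}: genotype dosage outside {{0,1,2}}")
    panel = ReferencePanel(snps=meta, dosages=dosages)
    _warn_monomorphic(panel, path)
    return panel


def _warn_monomorphic(panel: ReferencePanel, path: Path) -> None:
    n_mono = int(panel.monomorphic.sum())
    if n_mono:
        logger.info("%s: %d monomorphic SNPs flagged (excluded from LD)", path, n_mono)


# ---------------------------------------------------------------------------
# Expression datasets


def read_expression_dataset(
    matrix_path: str | Path,
    labels_path: str | Path,
    mapping_path: str | Path | None = None,
    dataset_name: str = "",
) -> ExpressionDataset:
    """Read a transcripts x samples log2 expression matrix with labels.

    The labels file is two tab-separated columns (sample id, case|control).
    The optional mapping file is two tab-separated columns (alias, official
    symbol); transcripts whose id has no mapping entry keep an empty symbol
    and are excluded from downstream screening. Without a mapping file the
    transcript id itself is taken as the symbol.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    labels_df = pd.read_csv(
        labels_path, sep="\t", header=None, names=["sample", "group"], dtype=str
    )
    labels = dict(zip(labels_df["sample"], labels_df["group"].str.strip().str.lower()))
    bad = set(labels.values()) - {"case", "control"}
    if bad:
        raise FormatError(f"{labels_path}: group labels must be case|control, got {bad}")
    missing = [s for s in mat.columns if s not in labels]
    if missing:
        raise FormatError(f"{labels_path}: samples missing from labels: {missing[:5]}")
    group_labels = [labels[s] for s in mat.columns]
    for grp in ("case", "control"):
        if group_labels.count(grp) < 2:
            raise FormatError(f"{matrix_path}: fewer than 2 {grp} samples")

    transcript_ids = [str(t) for t in mat.index]
    if mapping_path is not None:
        mp = pd.read_csv(
            mapping_path, sep="\t", header=None, names=["alias", "symbol"], dtype=str
        )
        mapping = dict(zip(mp["alias"], mp["symbol"]))
        gene_symbols = [mapping.get(t, "") for t in transcript_ids]
        n_unmapped = gene_symbols.count("")
        if n_unmapped:
            logger.info(
                "%s: %d transcripts with no official symbol (kept, excluded downstream)",
                matrix_path,
                n_unmapped,
            )
    else:
        gene_symbols = list(transcript_ids)

    return ExpressionDataset(
        values=mat.to_numpy(dtype=float),
        transcript_ids=transcript_ids,
        gene_symbols=gene_symbols,
        group_labels=group_labels,
        dataset_name=dataset_name or Path(matrix_path).stem,
        sample_ids=[str(c) for c in mat.columns],
    )


# ---------------------------------------------------------------------------
# Result tables

_FLOAT_FMT = "{:.5E}"  # 6 significant digits, scientific


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with floats in 6-significant-digit
    scientific notation, so reruns compare bit-identically."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else _FLOAT_FMT.format(v)
            )
    out.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Re-read a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
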