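"""Readers, writers and domain containers shared by every analysis stage.

All genomic coordinates are kept in the BED convention (0-based, half-open)
internally, with one exception: variant positions are stored 1-based exactly
as they appear in the VCF and converted where a comparison against feature
coordinates is needed.  Phenotype files follow the QTLtools dialect of BED:
six annotation columns (``#chr start end id gid strand``) followed by one
column per sample.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("crdscan")

_VARIANT_COLS = ["variant_id", "chrom", "pos", "ref", "alt", "maf"]
_FEATURE_COLS = ["feature_id", "chrom", "start", "end", "strand", "group_id"]

PHENOTYPE_KINDS = ("raw_count", "quantified", "normalized")


def _chrom_sort_key(chroms) -> np.ndarray:
    """Stable lexicographic order for chromosome names."""
    return np.asarray([str(c) for c in chroms])


@dataclass
class GenotypeMatrix:
    """Dosage-coded biallelic genotypes for a cohort.

    ``dosages`` is samples x variants with entries in [0, 2] (NaN allowed for
    missing calls); ``variants`` carries one row per variant with 1-based
    positions and the minor-allele frequency computed from the dosages.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        vid = self.variants["variant_id"]
        if vid.duplicated().any():
            raise ValueError("duplicate variant ids")
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        order = self.variants.sort_values(
            ["chrom", "pos"], kind="stable"
        ).index.to_numpy()
        if not np.array_equal(order, np.arange(len(order))):
            raise ValueError("variants must be sorted by (chrom, pos)")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < -1e-9 or np.nanmax(
                self.dosages, initial=0.0
            ) > 2 + 1e-9:
                raise ValueError("dosages outside [0, 2]")
        maf = compute_maf(self.dosages)
        if not np.allclose(maf, self.variants["maf"].to_numpy(), atol=1e-9):
            raise ValueError("stored maf does not match dosages")

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        d = self.dosages[idx]
        v = self.variants.copy()
        v["maf"] = compute_maf(d)
        return GenotypeMatrix(list(sample_ids), v, d)


def compute_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per variant from a samples x variants dosage matrix."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(np.asarray(dosages, dtype=float), axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


@dataclass
class PhenotypeMatrix:
    """Samples x features matrix of molecular quantifications.

    Features (chromatin peaks, genes or CRD activities) carry BED coordinates
    and are kept sorted by (chrom, start).  ``kind`` distinguishes raw counts
    from quantified and covariate-corrected/normalized values so downstream
    stages can enforce which representation they require.
    """

    sample_ids: list[str]
    features: pd.DataFrame
    values: np.ndarray
    kind: str = "quantified"

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.features = self.features.reset_index(drop=True)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def validate(self) -> None:
        if self.kind not in PHENOTYPE_KINDS:
            raise ValueError(f"unknown phenotype kind {self.kind!r}")
        if self.features["feature_id"].duplicated().any():
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.values.shape != (len(self.sample_ids), len(self.features)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.features)} features"
            )
        if (self.features["start"] >= self.features["end"]).any():
            raise ValueError("feature with start >= end")
        order = self.features.sort_values(
            ["chrom", "start"], kind="stable"
        ).index.to_numpy()
        if not np.array_equal(order, np.arange(len(order))):
            raise ValueError("features must be sorted by (chrom, start)")
        if self.kind == "raw_count":
            finite = self.values[np.isfinite(self.values)]
            if (finite < 0).any() or not np.allclose(finite, np.round(finite)):
                raise ValueError("raw_count values must be non-negative integers")

    def feature_index(self, feature_ids) -> np.ndarray:
        lookup = {f: i for i, f in enumerate(self.features["feature_id"])}
        try:
            return np.asarray([lookup[f] for f in feature_ids], dtype=int)
        except KeyError as e:  # pragma: no cover - message only
            raise KeyError(f"unknown feature id {e.args[0]!r}") from None

    def subset_samples(self, sample_ids) -> "PhenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return PhenotypeMatrix(
            list(sample_ids), self.features.copy(), self.values[idx], self.kind
        )

    def anchors(self) -> np.ndarray:
        """Strand-aware anchor (TSS for genes) per feature, 0-based."""
        start = self.features["start"].to_numpy()
        end = self.features["end"].to_numpy()
        strand = self.features["strand"].to_numpy()
        return np.where(strand == "-", end - 1, start)


@dataclass
class SampleMetadata:
    """Per-sample disease status plus named numeric covariates."""

    table: pd.DataFrame  # columns: sample_id, status, <covariate...>

    def __post_init__(self):
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        bad = set(self.table["status"]) - {"case", "control"}
        if bad:
            raise ValueError(f"invalid status values: {bad}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def status_codes(self, sample_ids=None) -> np.ndarray:
        """Binary status, case = 1, in the requested sample order."""
        t = self.table.set_index("sample_id")
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        return (t.loc[ids, "status"] == "case").to_numpy().astype(int)

    def covariate_matrix(self, sample_ids=None) -> tuple[list[str], np.ndarray]:
        names = [c for c in self.table.columns if c not in ("sample_id", "status")]
        t = self.table.set_index("sample_id")
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        return names, t.loc[ids, names].to_numpy(dtype=float)


class IntervalSet:
    """Half-open genomic intervals with overlap queries, per chromosome."""

    def __init__(self, intervals, label: str | None = None):
        self.label = label
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        rows: dict[str, list[tuple[int, int]]] = {}
        n = 0
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            rows.setdefault(str(chrom), []).append((int(start), int(end)))
            n += 1
        self.n_intervals = n
        for chrom, ivs in rows.items():
            ivs.sort()
            s = np.asarray([i[0] for i in ivs])
            e = np.asarray([i[1] for i in ivs])
            self._by_chrom[chrom] = (s, e)

    def __len__(self) -> int:
        return self.n_intervals

    def overlaps(self, chrom, start, end) -> bool:
        """True iff [start, end) intersects any stored interval by >= 1 bp."""
        if chrom not in self._by_chrom:
            return False
        s, e = self._by_chrom[chrom]
        return bool(np.any((s < end) & (e > start)))

    def containing(self, chrom, pos) -> tuple[int, int] | None:
        """The first interval containing ``pos`` (0-based), or None."""
        if chrom not in self._by_chrom:
            return None
        s, e = self._by_chrom[chrom]
        hit = np.nonzero((s <= pos) & (pos < e))[0]
        if hit.size == 0:
            return None
        i = hit[0]
        return int(s[i]), int(e[i])

    def intervals(self):
        for chrom in sorted(self._by_chrom):
            s, e = self._by_chrom[chrom]
            for a, b in zip(s, e):
                yield chrom, int(a), int(b)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_genotypes(path) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix`.

    Dosages come from the ``DS`` FORMAT field when present, otherwise from
    the ALT-allele count of ``GT``.  Multiallelic records are skipped with a
    logged count; missing calls become NaN.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    cols = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(len(samples), -1)[:, 0]
            d = np.where(d < -0.5, np.nan, d)  # cyvcf2 missing sentinel
        else:
            g = np.asarray(var.genotypes, dtype=float)[:, :2]
            g = np.where(g < 0, np.nan, np.clip(g, 0, 1))
            d = g.sum(axis=1)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        rows.append((vid, var.CHROM, int(var.POS), var.REF, var.ALT[0]))
        cols.append(d)
    if skipped:
        log.info("read_genotypes: skipped %d non-biallelic records", skipped)
    if not cols:
        raise ValueError(f"no usable biallelic variants in {path}")
    dosages = np.column_stack(cols)
    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    order = variants.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    variants = variants.iloc[order].reset_index(drop=True)
    dosages = dosages[:, order]
    variants["maf"] = compute_maf(dosages)
    return GenotypeMatrix(samples, variants, dosages)


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF with GT:DS fields."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        chroms = pd.unique(gm.variants["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, row in gm.variants.iterrows():
            cells = []
            for d in gm.dosages[:, j]:
                if np.isnan(d):
                    cells.append("./.:.")
                    continue
                g = int(round(d))
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[min(max(g, 0), 2)]
                cells.append(f"{gt}:{d:.10g}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT:DS\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Phenotype BED (QTLtools dialect)
# ---------------------------------------------------------------------------

def read_phenotype_bed(path, kind: str = "quantified") -> PhenotypeMatrix:
    """Read a QTLtools-style phenotype BED (``#chr start end id gid strand`` +
    one column per sample)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 7 or not header[0].lstrip("#").lower().startswith("chr"):
        raise ValueError(f"{path}: not a phenotype BED (bad header)")
    sample_ids = header[6:]
    df = pd.read_csv(
        path, sep="\t", skiprows=1, header=None, dtype={0: str},
        na_values=["NA"], float_precision="round_trip",
    )
    if df.shape[1] != len(header):
        raise ValueError(
            f"{path}: ragged rows ({df.shape[1]} columns, header has {len(header)})"
        )
    features = df.iloc[:, :6].copy()
    features.columns = ["chrom", "start", "end", "feature_id", "group_id", "strand"]
    features = features[_FEATURE_COLS]
    if features["feature_id"].duplicated().any():
        dup = features["feature_id"][features["feature_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    values = df.iloc[:, 6:].to_numpy(dtype=float).T
    return PhenotypeMatrix(sample_ids, features, values, kind)


def write_phenotype_bed(pm: PhenotypeMatrix, path) -> None:
    path = Path(path)
    feats = pm.features
    with open(path, "w") as fh:
        fh.write(
            "#chr\tstart\tend\tid\tgid\tstrand\t" + "\t".join(pm.sample_ids) + "\n"
        )
        for j in range(pm.n_features):
            f = feats.iloc[j]
            vals = "\t".join(_fmt_value(v) for v in pm.values[:, j])
            fh.write(
                f"{f.chrom}\t{int(f.start)}\t{int(f.end)}\t{f.feature_id}"
                f"\t{f.group_id}\t{f.strand}\t{vals}\n"
            )


def _fmt_value(v: float) -> str:
    if np.isnan(v):
        return "NA"
    if float(v).is_integer() and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


# ---------------------------------------------------------------------------
# Metadata, intervals, results tables, config
# ---------------------------------------------------------------------------

def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_bed_intervals(path, label=None) -> IntervalSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    return IntervalSet(
        [(r[0], int(r[1]), int(r[2])) for r in df.itertuples(index=False)], label
    )


def write_bed_intervals(iset: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in iset.intervals():
            fh.write(f"{chrom}\t{s}\t{e}\n")


def write_results_table(records, path, columns=None) -> None:
    """Write result records as a TSV with a fixed column order.

    ``records`` is either a DataFrame or a list of dataclass instances of one
    type.  Floats are written at 6 significant digits; row order is preserved
    (callers emit deterministic orders).
    """
    if isinstance(records, pd.DataFrame):
        df = records if columns is None else records[list(columns)]
    else:
        records = list(records)
        if records:
            t0 = type(records[0])
            if not all(type(r) is t0 for r in records):
                raise TypeError("mixed record types in results table")
            if not dataclasses.is_dataclass(t0):
                raise TypeError("records must be dataclasses or a DataFrame")
            cols = [f.name for f in dataclasses.fields(t0)]
            df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)
        else:
            df = pd.DataFrame(columns=list(columns) if columns else [])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def setup_logging(level=logging.INFO, logfile=None) -> None:
    handlers = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
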