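"""Readers, writers, and in-memory containers for the pipeline's standard formats.

Three containers flow through the whole pipeline:

``GenotypeMatrix``
    lines x biallelic markers as minor-allele dosage {0, 1, 2} with an
    explicit missing mask and per-marker metadata (chromosome, position,
    minor-allele frequency).
``TrialTable``
    plot-level field records from an augmented block design: entry,
    environment, block, check flag/identity, and one named response.
``SpectralRecord``
    per-plot canopy reflectance by wavelength (nm), tagged with a growth
    stage, plus any derived spectral index values.

Supported on-disk formats: VCF 4.x (GT field only, read through cyvcf2),
HapMap-like TSV, a plain dosage TSV, and CSV for trials and reflectance.
All downstream modules consume only the in-memory containers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # sentinel in the int8 dosage array

#: canonical growth-stage labels: heading, early grain fill, late grain fill
STAGES = ("Hd", "Gf1", "Gf2")

_STAGE_ALIASES = {
    "hd": "Hd",
    "heading": "Hd",
    "gf1": "Gf1",
    "grainfill1": "Gf1",
    "early_grain_fill": "Gf1",
    "milk": "Gf1",
    "gf2": "Gf2",
    "grainfill2": "Gf2",
    "late_grain_fill": "Gf2",
    "soft_dough": "Gf2",
}


class FormatError(ValueError):
    """Malformed file content (bad header, wrong dialect)."""


class ValidationError(ValueError):
    """Well-formed file whose content violates a container invariant."""


def normalize_stage(label: str) -> str:
    """Map a free-form growth-stage label onto {Hd, Gf1, Gf2}."""
    key = str(label).strip().lower().replace("-", "_").replace(" ", "_")
    if key in _STAGE_ALIASES:
        return _STAGE_ALIASES[key]
    raise ValidationError(
        f"unknown growth stage {label!r}; accepted labels map onto {STAGES}"
    )


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Lines x markers minor-allele dosage matrix with missing mask.

    ``dosage[i, j]`` counts copies of the *minor* allele of marker ``j``
    carried by line ``i`` (0, 1 or 2); missing calls are stored as -1 and
    exposed through :attr:`missing`. Orientation toward the minor allele is
    enforced at construction: markers whose stored allele frequency exceeds
    0.5 are flipped (dosage -> 2 - dosage).
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    dosage: np.ndarray  # int8, (n_lines, n_markers), -1 = missing
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]
    #: markers re-oriented (dosage -> 2 - dosage) relative to the source
    #: coding; lets two panels read from the same coordinate system be
    #: orientation-aligned even when their within-panel minor alleles differ
    flipped: np.ndarray = field(default=None)  # type: ignore[assignment]
    #: True after imputation: dosage is float64 in [0, 2], no missing calls
    fractional: bool = False

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        if self.fractional:
            self.dosage = np.asarray(self.dosage, dtype=np.float64)
        else:
            self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if self.fractional:
            if np.isnan(self.dosage).any():
                raise ValidationError("fractional matrix must not contain missing calls")
            if self.dosage.min() < 0 or self.dosage.max() > 2:
                raise ValidationError("fractional dosage must lie in [0, 2]")
        else:
            bad = ~np.isin(self.dosage, (MISSING, 0, 1, 2))
            if bad.any():
                raise ValidationError("dosage values must be in {0, 1, 2} or missing")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValidationError("line_ids must be unique")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValidationError("marker_ids must be unique")
        if self.chrom is not None:
            self.chrom = np.asarray(self.chrom, dtype=object)
        if self.pos is not None:
            self.pos = np.asarray(self.pos, dtype=np.int64)
        prior_flips = (np.zeros(len(self.marker_ids), dtype=bool)
                       if self.flipped is None
                       else np.asarray(self.flipped, dtype=bool).copy())
        if self.fractional:
            self.flipped = prior_flips
        else:
            new_flips = self._orient_minor()
            self.flipped = prior_flips ^ new_flips
        computed = self.compute_maf()
        if self.maf is None:
            self.maf = computed
        else:
            self.maf = np.asarray(self.maf, dtype=float)
            if not np.allclose(self.maf, computed, atol=1e-12, equal_nan=True):
                raise ValidationError("stored maf disagrees with dosages")

    # -- derived views ------------------------------------------------------

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing(self) -> np.ndarray:
        if self.fractional:
            return np.zeros_like(self.dosage, dtype=bool)
        return self.dosage == MISSING

    def compute_maf(self) -> np.ndarray:
        """Minor-allele frequency per marker over non-missing calls."""
        p = self._allele_freq()
        return np.minimum(p, 1.0 - p)

    def _allele_freq(self) -> np.ndarray:
        d = self.dosage_float()
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(d, axis=0) / 2.0  # NaN where fully missing

    def _orient_minor(self) -> np.ndarray:
        p = self._allele_freq()
        flip = p > 0.5
        if flip.any():
            cols = self.dosage[:, flip]
            flipped = np.where(cols == MISSING, MISSING, 2 - cols)
            self.dosage[:, flip] = flipped.astype(np.int8)
        return flip

    # -- subsetting ---------------------------------------------------------

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            line_ids=self.line_ids,
            marker_ids=self.marker_ids[idx],
            dosage=self.dosage[:, idx].copy(),
            chrom=None if self.chrom is None else self.chrom[idx],
            pos=None if self.pos is None else self.pos[idx],
            flipped=self.flipped[idx],
            fractional=self.fractional,
        )

    def take_lines(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            line_ids=self.line_ids[idx],
            marker_ids=self.marker_ids,
            dosage=self.dosage[idx, :].copy(),
            chrom=self.chrom,
            pos=self.pos,
            flipped=self.flipped.copy(),
            fractional=self.fractional,
        )

    def dosage_float(self) -> np.ndarray:
        """Dosage as float with NaN at missing calls."""
        if self.fractional:
            return self.dosage.copy()
        d = self.dosage.astype(float)
        d[d == MISSING] = np.nan
        return d


# ---------------------------------------------------------------------------
# TrialTable
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = ["entry_id", "environment_id", "block_id", "is_check", "check_id", "value"]


@dataclass
class TrialTable:
    """Plot-level records of one response from an augmented field trial.

    ``data`` holds one row per plot with columns
    ``entry_id, environment_id, block_id, is_check, check_id, value``;
    ``check_id`` is empty exactly where ``is_check`` is False, and ``value``
    is NaN for missing plots (kept, never silently dropped).
    """

    data: pd.DataFrame
    response: str = "yield"
    units: str = "t/ha"

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in _TRIAL_COLUMNS if c not in df.columns]
        if missing_cols:
            raise FormatError(f"trial table missing columns: {missing_cols}")
        df = df[_TRIAL_COLUMNS].copy()
        df["is_check"] = df["is_check"].astype(bool)
        df["check_id"] = df["check_id"].fillna("").astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        bad = df.loc[~df["is_check"], "check_id"] != ""
        if bad.any():
            raise ValidationError("check_id present on a non-check row")
        nocid = df.loc[df["is_check"], "check_id"] == ""
        if nocid.any():
            raise ValidationError("is_check row without a check_id")
        keys = df[["entry_id", "environment_id", "block_id"]].astype(str).agg("|".join, axis=1)
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise ValidationError(f"duplicate (entry, environment, block) key: {dup}")
        finite = df["value"].to_numpy(dtype=float)
        if np.isinf(finite).any():
            raise ValidationError("non-finite (inf) response value")
        self.data = df.reset_index(drop=True)

    @property
    def environments(self) -> list:
        return sorted(self.data["environment_id"].unique().tolist())

    @property
    def entries(self) -> list:
        """Test-entry identifiers (checks excluded), sorted."""
        return sorted(self.data.loc[~self.data["is_check"], "entry_id"].unique().tolist())

    def subset_environment(self, env) -> "TrialTable":
        sub = self.data[self.data["environment_id"] == env]
        if sub.empty:
            raise ValidationError(f"environment {env!r} not present")
        return TrialTable(sub.copy(), response=self.response, units=self.units)

    def validate_blocks_have_checks(self) -> None:
        """Augmented adjustment needs >=1 check plot in every block."""
        grp = self.data.groupby(["environment_id", "block_id"])["is_check"].any()
        if not grp.all():
            bad = grp[~grp].index.tolist()
            raise ValidationError(f"blocks without any check plot: {bad}")


# ---------------------------------------------------------------------------
# SpectralRecord
# ---------------------------------------------------------------------------


@dataclass
class SpectralRecord:
    """Canopy reflectance for one plot at one growth stage.

    ``reflectance`` maps wavelength in nm -> reflectance fraction in [0, 1];
    ``indices`` caches derived spectral-index values (see the sri module).
    """

    plot_key: tuple  # (entry_id, environment_id, block_id)
    stage: str
    reflectance: dict
    indices: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stage = normalize_stage(self.stage)
        self.reflectance = {int(k): float(v) for k, v in self.reflectance.items()}
        for nm, r in self.reflectance.items():
            if not (0.0 <= r <= 1.0):
                raise ValidationError(
                    f"reflectance {r} at {nm} nm outside [0, 1] for plot {self.plot_key}"
                )


# ---------------------------------------------------------------------------
# Genotype readers
# ---------------------------------------------------------------------------


def read_genotype_matrix(path, format: str, drop_non_biallelic: bool = False) -> GenotypeMatrix:
    """Read a genotype file into a :class:`GenotypeMatrix`.

    format : one of ``vcf``, ``hapmap_tsv``, ``dosage_tsv``. Marker order
    follows file order; dosages are re-oriented toward the minor allele.
    Multi-allelic sites raise unless ``drop_non_biallelic`` is set.
    """
    if format == "vcf":
        return _read_vcf(path, drop_non_biallelic)
    if format == "hapmap_tsv":
        return _read_hapmap(path, drop_non_biallelic)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise FormatError(f"unknown genotype format {format!r}")


def _read_vcf(path, drop_non_biallelic: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, mids, chroms, poss = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1 or var.ALT[0] in (".", ""):
            if drop_non_biallelic:
                continue
            raise ValidationError(
                f"non-biallelic site at {var.CHROM}:{var.POS}; pass drop_non_biallelic=True to drop"
            )
        gt = np.asarray(var.gt_types)  # 0=hom ref, 1=het, 2=hom alt, 3=missing
        dos = np.where(gt == 3, MISSING, gt).astype(np.int8)
        rows.append(dos)
        mids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if not rows:
        raise FormatError(f"no usable biallelic sites in {path}")
    dosage = np.stack(rows, axis=1)
    return GenotypeMatrix(
        line_ids=np.array(samples, dtype=object),
        marker_ids=np.array(mids, dtype=object),
        dosage=dosage,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
    )


_HAPMAP_FIXED = ["rs", "alleles", "chrom", "pos"]


def _read_hapmap(path, drop_non_biallelic: bool) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for c in _HAPMAP_FIXED:
        if c not in df.columns:
            raise FormatError(f"HapMap TSV missing required column {c!r}")
    samples = [c for c in df.columns if c not in _HAPMAP_FIXED]
    if not samples:
        raise FormatError("HapMap TSV has no sample columns")
    keep_rows, dosage_rows = [], []
    for i, row in df.iterrows():
        alleles = str(row["alleles"]).split("/")
        if len(alleles) != 2:
            if drop_non_biallelic:
                continue
            raise ValidationError(f"non-biallelic alleles {row['alleles']!r} at row {i}")
        a, b = alleles
        dos = np.empty(len(samples), dtype=np.int8)
        for k, s in enumerate(samples):
            call = str(row[s]).upper()
            if call in ("NN", "N", "NA", "./.", ".", ""):
                dos[k] = MISSING
            elif len(call) == 2:
                dos[k] = sum(ch == b for ch in call)
            else:
                raise FormatError(f"unparseable HapMap call {row[s]!r} (sample {s}, row {i})")
        keep_rows.append(i)
        dosage_rows.append(dos)
    sub = df.loc[keep_rows]
    return GenotypeMatrix(
        line_ids=np.array(samples, dtype=object),
        marker_ids=sub["rs"].to_numpy(dtype=object),
        dosage=np.stack(dosage_rows, axis=1),
        chrom=sub["chrom"].to_numpy(dtype=object),
        pos=sub["pos"].astype(np.int64).to_numpy(),
    )


def _read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"empty dosage TSV {path}")
    vals = df.to_numpy(dtype=float)
    dosage = np.where(np.isnan(vals), MISSING, vals)
    if not np.isin(dosage, (MISSING, 0, 1, 2)).all():
        raise ValidationError("dosage TSV contains values outside {0, 1, 2, NA}")
    return GenotypeMatrix(
        line_ids=df.index.to_numpy(dtype=object),
        marker_ids=df.columns.to_numpy(dtype=object),
        dosage=dosage.astype(np.int8),
    )


# ---------------------------------------------------------------------------
# Genotype writers (round-trip counterparts)
# ---------------------------------------------------------------------------


def write_genotype_matrix(g: GenotypeMatrix, path, format: str) -> None:
    """Write ``g`` to disk; ``read_genotype_matrix`` round-trips bit-exactly."""
    if format == "dosage_tsv":
        d = g.dosage_float()
        pd.DataFrame(d, index=g.line_ids, columns=g.marker_ids).to_csv(path, sep="\t")
    elif format == "vcf":
        _write_vcf(g, path)
    else:
        raise FormatError(f"unsupported write format {format!r}")


def _write_vcf(g: GenotypeMatrix, path) -> None:
    # minimal GT-only VCF 4.2; REF is the major allele so ALT dosage = minor dosage
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    chroms = g.chrom if g.chrom is not None else ["0"] * g.n_markers
    # a contig line per distinct chromosome keeps htslib readers quiet
    for c in dict.fromkeys(str(c) for c in chroms):
        buf.write(f"##contig=<ID={c}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(str(s) for s in g.line_ids) + "\n")
    gtmap = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    poss = g.pos if g.pos is not None else np.arange(1, g.n_markers + 1)
    for j in range(g.n_markers):
        calls = "\t".join(gtmap[int(v)] for v in g.dosage[:, j])
        buf.write(
            f"{chroms[j]}\t{int(poss[j])}\t{g.marker_ids[j]}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Trial and reflectance tables
# ---------------------------------------------------------------------------


def read_trial_table(path, response: str = "yield", units: str = "t/ha") -> TrialTable:
    """Read a plot-level phenotype CSV into a :class:`TrialTable`."""
    df = pd.read_csv(path, dtype={"entry_id": str, "environment_id": str, "block_id": str,
                                  "check_id": str})
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trial CSV {path} missing columns {missing}")
    return TrialTable(df, response=response, units=units)


def write_trial_table(trial: TrialTable, path) -> None:
    trial.data.to_csv(path, index=False)


def read_reflectance_table(path, percent_scale: bool = False) -> list[SpectralRecord]:
    """Read a plot x stage reflectance CSV into :class:`SpectralRecord` objects.

    Band columns are named by wavelength in nm. With ``percent_scale`` the
    values are divided by 100 before validation against [0, 1].
    """
    df = pd.read_csv(path, dtype={"entry_id": str, "environment_id": str, "block_id": str})
    key_cols = ["entry_id", "environment_id", "block_id", "stage"]
    missing = [c for c in key_cols if c not in df.columns]
    if missing:
        raise FormatError(f"reflectance CSV {path} missing columns {missing}")
    band_cols = [c for c in df.columns if c not in key_cols]
    bands = []
    for c in band_cols:
        try:
            bands.append((int(c), c))
        except ValueError:
            raise FormatError(f"non-wavelength column {c!r} in reflectance CSV")
    records = []
    for _, row in df.iterrows():
        refl = {}
        for nm, col in bands:
            v = float(row[col])
            if percent_scale:
                v /= 100.0
            refl[nm] = v
        records.append(
            SpectralRecord(
                plot_key=(row["entry_id"], row["environment_id"], row["block_id"]),
                stage=row["stage"],
                reflectance=refl,
            )
        )
    return records


def write_reflectance_table(records: list[SpectralRecord], path) -> None:
    bands = sorted({nm for r in records for nm in r.reflectance})
    rows = []
    for r in records:
        row = {
            "entry_id": r.plot_key[0],
            "environment_id": r.plot_key[1],
            "block_id": r.plot_key[2],
            "stage": r.stage,
        }
        row.update({str(nm): r.reflectance.get(nm, np.nan) for nm in bands})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
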