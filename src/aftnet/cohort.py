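"""Subject-level genotype/clinical survival data: containers and encoders.

A :class:`Cohort` couples a numeric feature matrix (binary SNP carrier
indicators, APOE allele indicators, MMSE, sex, ...) with right-censored
survival outcomes.  Genotypes can come from a delimited feature table or be
extracted from a VCF by ``chrom:pos:ref>alt`` coordinates.

Encoding conventions
--------------------
* APOE genotype labels like ``"E3/E4"`` become three carrier indicators
  (carries E2, carries E3, carries E4).
* Each biallelic SNP becomes two carrier indicators (carries ref, carries
  alt): hom-ref -> (1, 0), het -> (1, 1), hom-alt -> (0, 1).  A single
  alt-carrier column is available via ``mode="alt_carrier"``.
* Variant matching against a VCF is strict on (chrom, pos, ref, alt): no
  allele flipping or strand complementing — silent mismatches are worse
  than explicit errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VariantSpec",
    "Cohort",
    "FoldAssignment",
    "encode_apoe",
    "encode_snp_indicators",
    "read_feature_table",
    "extract_variants_vcf",
    "stratified_kfold",
]

APOE_ALLELES = ("E2", "E3", "E4")


@dataclass(frozen=True)
class VariantSpec:
    """A biallelic variant keyed by 1-based VCF coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = None
    gene: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) is not a variant")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def label(self) -> str:
        stem = self.gene or self.rsid or str(self)
        if self.gene and self.rsid:
            stem = f"{self.gene}_{self.rsid}"
        return stem


def encode_apoe(genotype_label: str) -> tuple[int, int, int]:
    """APOE genotype label -> (carries E2, carries E3, carries E4).

    The label is an unordered allele pair such as ``"E3/E4"``; an indicator
    is 1 iff that allele appears at least once, so ``"E2/E2"`` -> (1,0,0).
    """
    if not isinstance(genotype_label, str) or "/" not in genotype_label:
        raise ValueError(f"APOE genotype must look like 'E3/E4', got {genotype_label!r}")
    alleles = [a.strip().upper() for a in genotype_label.split("/")]
    if len(alleles) != 2:
        raise ValueError(f"APOE genotype must be a diploid pair, got {genotype_label!r}")
    for a in alleles:
        if a not in APOE_ALLELES:
            raise ValueError(f"unknown APOE allele token {a!r} in {genotype_label!r}")
    return tuple(int(a in alleles) for a in APOE_ALLELES)


def _normalize_calls(calls):
    """Accept GT strings ('0/1', './.') or alt-allele counts; return counts.

    Returns an int array with values in {0, 1, 2} and -1 for missing.
    """
    arr = np.asarray(calls)
    if arr.dtype.kind in "iuf":
        counts = arr.astype(float)
        ok = np.isin(counts, (0.0, 1.0, 2.0, -1.0))
        if not ok.all():
            bad = counts[~ok][0]
            raise ValueError(f"allele count outside {{0,1,2,-1}}: {bad!r}")
        return counts.astype(int)
    counts = np.empty(arr.shape, dtype=int)
    for i, raw in np.ndenumerate(arr):
        s = str(raw).replace("|", "/")
        if s in (".", "./.", ".|."):
            counts[i] = -1
            continue
        parts = s.split("/")
        if len(parts) != 2 or any(p not in ("0", "1") for p in parts):
            raise ValueError(
                f"genotype call {raw!r} has an allele outside {{ref, alt}}"
            )
        counts[i] = sum(int(p) for p in parts)
    return counts


def encode_snp_indicators(calls, mode: str = "carrier_pair",
                          missing_policy: str = "impute_ref"):
    """Diploid calls for one variant -> binary carrier indicator columns.

    ``mode="carrier_pair"`` (default) yields two columns (carries ref,
    carries alt); ``mode="alt_carrier"`` a single carries-alt column.
    Missing calls are imputed to hom-ref with a warning (default) or raise
    under ``missing_policy="error"``.
    """
    counts = _normalize_calls(calls)
    missing = counts < 0
    if missing.any():
        if missing_policy == "error":
            raise ValueError(f"{int(missing.sum())} missing genotype call(s)")
        if missing_policy != "impute_ref":
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
        warnings.warn(
            f"imputing {int(missing.sum())} missing genotype call(s) to hom-ref",
            stacklevel=2,
        )
        counts = np.where(missing, 0, counts)
    ref_carrier = (counts <= 1).astype(int)
    alt_carrier = (counts >= 1).astype(int)
    if mode == "carrier_pair":
        return np.column_stack([ref_carrier, alt_carrier])
    if mode == "alt_carrier":
        return alt_carrier[:, None]
    raise ValueError(f"unknown mode {mode!r}")


class Cohort:
    """Feature matrix + survival outcomes, aligned by subject.

    `features` is a numeric DataFrame indexed by subject id; `time` and
    `event` are parallel arrays.  No missing values are allowed — apply a
    missingness policy during encoding, before construction.
    """

    def __init__(self, features: pd.DataFrame, time, event, subject_ids=None):
        if not isinstance(features, pd.DataFrame):
            features = pd.DataFrame(np.asarray(features, dtype=float))
            features.columns = [f"x{j}" for j in range(features.shape[1])]
        self.features = features.astype(float)
        self.time = np.asarray(time, dtype=float).ravel()
        self.event = np.asarray(event).astype(int).ravel()
        if subject_ids is not None:
            self.features.index = pd.Index(subject_ids, name="subject_id")
        elif self.features.index.name is None:
            self.features.index = pd.Index(
                [f"S{i:04d}" for i in range(len(self.features))], name="subject_id"
            )
        n = len(self.features)
        if not (self.time.shape[0] == self.event.shape[0] == n):
            raise ValueError("features, time and event must have equal length")
        if self.features.columns.duplicated().any():
            dup = self.features.columns[self.features.columns.duplicated()][0]
            raise ValueError(f"duplicate feature name {dup!r}")
        if self.features.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if np.any(self.time < 0):
            raise ValueError("negative survival time")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicator must be 0/1")

    # ---- accessors --------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def subject_ids(self) -> list:
        return list(self.features.index)

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    @property
    def event_fraction(self) -> float:
        return float(self.event.mean())

    def select_features(self, names) -> "Cohort":
        missing = [n for n in names if n not in self.features.columns]
        if missing:
            raise ValueError(f"unknown feature(s): {missing}")
        return Cohort(self.features[list(names)].copy(), self.time, self.event)

    def select_subjects(self, idx) -> "Cohort":
        idx = np.asarray(idx)
        return Cohort(self.features.iloc[idx].copy(), self.time[idx], self.event[idx])

    # ---- round-trip -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        out = self.features.copy()
        out.insert(0, "event", self.event)
        out.insert(0, "time", self.time)
        return out

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=True)

    def equals(self, other: "Cohort") -> bool:
        return (
            self.feature_names == other.feature_names
            and self.subject_ids == other.subject_ids
            and np.array_equal(self.time, other.time)
            and np.array_equal(self.event, other.event)
            and np.array_equal(self.X, other.X)
        )


def read_feature_table(
    path,
    time_col: str = "time",
    event_col: str = "event",
    id_col: str | None = "subject_id",
    feature_cols=None,
    sep: str | None = None,
) -> Cohort:
    """Read a delimited feature table (header row) into a :class:`Cohort`.

    Column roles are declared by name; every remaining column is a feature
    unless `feature_cols` narrows the selection.  The delimiter is sniffed
    from the extension when not given (.tsv -> tab, else comma).
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in (time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    ids = None
    if id_col is not None and id_col in df.columns:
        ids = df[id_col].astype(str).tolist()
        df = df.drop(columns=[id_col])
    if feature_cols is None:
        feature_cols = [c for c in df.columns if c not in (time_col, event_col)]
    feats = df[list(feature_cols)]
    bad = [c for c in feats.columns
           if not np.issubdtype(pd.to_numeric(feats[c], errors="coerce").dtype, np.number)
           or pd.to_numeric(feats[c], errors="coerce").isna().any()]
    if bad:
        raise ValueError(f"non-numeric or missing values in feature column(s) {bad}")
    time = pd.to_numeric(df[time_col], errors="coerce")
    event = pd.to_numeric(df[event_col], errors="coerce")
    if time.isna().any() or event.isna().any():
        raise ValueError("non-numeric cell in time/event column")
    if (time < 0).any():
        raise ValueError("negative time value in feature table")
    return Cohort(feats.astype(float), time.to_numpy(), event.to_numpy(),
                  subject_ids=ids)


def extract_variants_vcf(
    vcf_path,
    variants,
    on_missing_variant: str = "error",
    on_missing_genotype: str = "impute_ref",
) -> pd.DataFrame:
    """Extract alt-allele counts for requested variants from a VCF.

    Matching is strict on (chrom, pos, ref, alt); a multiallelic record
    matches only if the requested alt is among its ALT alleles, and a call
    carrying some *other* alt allele at that site is a validation error.
    Returns a samples x variants DataFrame of alt counts in {0, 1, 2}
    (missing calls resolved per `on_missing_genotype`).

    `on_missing_variant`: ``"error"`` (default) or ``"all_missing"`` — the
    latter records every call for the unmatched variant as missing and lets
    the genotype policy resolve them.
    """
    from cyvcf2 import VCF

    variants = list(variants)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    calls = {str(v): None for v in variants}
    wanted = {(str(v.chrom), int(v.pos)): [] for v in variants}
    for v in variants:
        wanted[(str(v.chrom), int(v.pos))].append(v)
    for rec in vcf:
        key = (str(rec.CHROM), int(rec.POS))
        if key not in wanted:
            continue
        for v in wanted[key]:
            if rec.REF != v.ref or v.alt not in list(rec.ALT):
                continue
            alt_idx = list(rec.ALT).index(v.alt) + 1
            counts = np.empty(len(samples), dtype=int)
            for i, gt in enumerate(rec.genotypes):
                alleles = [a for a in gt[:2]]
                if any(a not in (-1, 0, alt_idx) for a in alleles):
                    raise ValueError(
                        f"sample {samples[i]} at {v} carries an allele outside "
                        "{ref, alt} for the requested variant"
                    )
                if any(a == -1 for a in alleles):
                    counts[i] = -1
                else:
                    counts[i] = sum(int(a == alt_idx) for a in alleles)
            calls[str(v)] = counts
    missing_vars = [k for k, c in calls.items() if c is None]
    if missing_vars:
        if on_missing_variant == "error":
            raise ValueError(f"variant(s) not found in VCF: {missing_vars}")
        if on_missing_variant != "all_missing":
            raise ValueError(f"unknown on_missing_variant {on_missing_variant!r}")
        for k in missing_vars:
            calls[k] = np.full(len(samples), -1, dtype=int)
    table = pd.DataFrame(calls, index=pd.Index(samples, name="sample"))
    if (table.to_numpy() < 0).any():
        if on_missing_genotype == "error":
            raise ValueError("missing genotype call(s) present")
        warnings.warn("imputing missing genotype call(s) to hom-ref", stacklevel=2)
        table = table.mask(table < 0, 0)
    return table


@dataclass
class FoldAssignment:
    """Event-stratified partition of subjects into k folds."""

    fold_of_subject: np.ndarray
    k: int
    seed: int

    def __post_init__(self):
        self.fold_of_subject = np.asarray(self.fold_of_subject, dtype=int)
        sizes = np.bincount(self.fold_of_subject, minlength=self.k)
        if sizes.size != self.k or np.any(sizes == 0):
            raise ValueError("every fold must be non-empty")

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.fold_of_subject, minlength=self.k)

    def train_test_indices(self, fold: int):
        test = np.flatnonzero(self.fold_of_subject == fold)
        train = np.flatnonzero(self.fold_of_subject != fold)
        return train, test


def stratified_kfold(event, k: int, seed: int = 0) -> FoldAssignment:
    """Assign subjects to k folds, stratified on the event indicator.

    Shuffled events and censored subjects are dealt round-robin with a
    shared cycling counter, so per-fold event counts are within 1 of the
    proportional share *and* total fold sizes differ by at most 1.
    """
    if hasattr(event, "event"):  # accept a Cohort
        event = event.event
    d = np.asarray(event).astype(int).ravel()
    n = d.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of subjects n={n}")
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    counter = int(rng.integers(k))
    for group in (rng.permutation(np.flatnonzero(d == 1)),
                  rng.permutation(np.flatnonzero(d == 0))):
        for idx in group:
            fold[idx] = counter % k
            counter += 1
    return FoldAssignment(fold_of_subject=fold, k=k, seed=seed)
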