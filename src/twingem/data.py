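"""Twin-cohort data model: individuals, pairs, CSV ingestion, imputation,
and residualization.

A cohort is one row per individual with canonical columns

    person_id, pair_id, zygosity, sex, age, bmi, walkability,
    work_employed, edu_high, lives_with_partner, deprivation_z

Pairing is by ``pair_id`` (at most two members); within a pair, twin order
is canonicalized by sorting on ``person_id`` so that all downstream
likelihoods are evaluated on a deterministic ordering.  Individuals with a
missing phenotype are retained in the cohort and filtered at fit time, so
one cohort object serves every analysis stage.

Binary covariates are coded employed=1, bachelor-or-above=1,
with-partner=1, and sex is female=1.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MZ = "MZ"
DZ = "DZ"

#: phenotypes are never imputed; everything else in COVARIATE_COLUMNS may be
PHENOTYPE_COLUMNS = ("bmi", "walkability")
COVARIATE_COLUMNS = ("work_employed", "edu_high", "lives_with_partner", "deprivation_z")
BINARY_COVARIATES = ("work_employed", "edu_high", "lives_with_partner")

CANONICAL_COLUMNS = (
    "person_id",
    "pair_id",
    "zygosity",
    "sex",
    "age",
    "bmi",
    "walkability",
) + COVARIATE_COLUMNS

_NUMERIC_COLUMNS = ("age", "bmi", "walkability") + COVARIATE_COLUMNS


class CohortError(ValueError):
    """Raised for malformed cohort inputs (duplicate ids, bad codes, ...)."""


@dataclass(frozen=True)
class Individual:
    """One twin's phenotypes and covariates."""

    person_id: str
    pair_id: str
    zygosity: str
    sex: str  # "male" / "female"
    age: float
    bmi: float  # kg/m^2, NaN if missing
    walkability: float  # index units, NaN if missing
    work_employed: float
    edu_high: float
    lives_with_partner: float
    deprivation_z: float


@dataclass(frozen=True)
class TwinPair:
    """A pair record; ``twin2`` is None for singletons."""

    twin1: Individual
    twin2: Individual | None
    zygosity: str

    @property
    def pair_id(self) -> str:
        return self.twin1.pair_id

    def complete_for(self, phenotypes: Sequence[str]) -> bool:
        """True iff both twins are present with all ``phenotypes`` non-missing."""
        if self.twin2 is None:
            return False
        for ph in phenotypes:
            if np.isnan(getattr(self.twin1, ph)) or np.isnan(getattr(self.twin2, ph)):
                return False
        return True


@dataclass
class TwinCohort:
    """A twin cohort: one row per individual plus the derived pair structure."""

    df: pd.DataFrame
    imputation_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise CohortError(f"cohort frame missing columns: {missing}")
        self._validate()

    # -- construction / validation ------------------------------------
    def _validate(self) -> None:
        df = self.df
        dup = df["person_id"][df["person_id"].duplicated()]
        if len(dup):
            raise CohortError(f"duplicate person_id: {sorted(set(dup))}")
        sizes = df.groupby("pair_id").size()
        too_big = sizes[sizes > 2]
        if len(too_big):
            raise CohortError(
                f"pair_id with more than 2 members: {sorted(too_big.index)}"
            )
        bad_zyg = set(df["zygosity"]) - {MZ, DZ}
        if bad_zyg:
            raise CohortError(f"unknown zygosity code(s): {sorted(bad_zyg)}")
        bad_sex = set(df["sex"]) - {"male", "female"}
        if bad_sex:
            raise CohortError(f"unknown sex code(s): {sorted(bad_sex)}")
        zyg_n = df.groupby("pair_id")["zygosity"].nunique()
        bad_pairs = zyg_n[zyg_n > 1].index.tolist()
        if bad_pairs:
            raise CohortError(f"pair(s) with discordant zygosity codes: {bad_pairs}")
        mz = df[df["zygosity"] == MZ]
        sex_n = mz.groupby("pair_id")["sex"].nunique()
        bad_sex_pairs = sex_n[sex_n > 1].index.tolist()
        if bad_sex_pairs:
            raise CohortError(
                f"MZ pair(s) with co-twins of different sex: {bad_sex_pairs}"
            )

    # -- derived views ------------------------------------------------
    @property
    def pairs(self) -> list[TwinPair]:
        out: list[TwinPair] = []
        for _, grp in self.df.groupby("pair_id", sort=True):
            grp = grp.sort_values("person_id")  # canonical twin order
            members = [Individual(**row[list(CANONICAL_COLUMNS)]) for _, row in grp.iterrows()]
            out.append(
                TwinPair(
                    twin1=members[0],
                    twin2=members[1] if len(members) == 2 else None,
                    zygosity=members[0].zygosity,
                )
            )
        return out

    @property
    def meta(self) -> dict:
        """Counts by zygosity and completeness (both phenotypes)."""
        df = self.df
        sizes = df.groupby("pair_id").size()
        complete_ids = sizes[sizes == 2].index
        zyg = df.drop_duplicates("pair_id").set_index("pair_id")["zygosity"]
        return {
            "n_individuals": int(len(df)),
            "n_pairs": int(len(sizes)),
            "n_complete_pairs": int(len(complete_ids)),
            "n_singletons": int((sizes == 1).sum()),
            "n_mz_pairs": int((zyg.loc[complete_ids] == MZ).sum()),
            "n_dz_pairs": int((zyg.loc[complete_ids] == DZ).sum()),
        }

    # -- fit-time array extraction ------------------------------------
    def paired_values(
        self, phenotype: str, zygosity: str | None = None
    ) -> np.ndarray:
        """(n, 2) array of co-twin values for complete pairs, canonical order.

        A pair is complete here iff both members exist and both have the
        requested phenotype non-missing.
        """
        df = self._two_member_frame()
        if zygosity is not None:
            df = df[df["zygosity"] == zygosity]
        wide = df.pivot_table(
            index="pair_id", columns="_order", values=phenotype, aggfunc="first"
        )
        if wide.empty:
            return np.empty((0, 2))
        wide = wide.reindex(columns=[1, 2])
        arr = wide.to_numpy(float)
        return arr[~np.isnan(arr).any(axis=1)]

    def paired_table(self, phenotypes: Sequence[str]) -> pd.DataFrame:
        """Wide per-pair frame (columns ``<ph>_1``, ``<ph>_2``, ``zygosity``)
        restricted to pairs complete on all ``phenotypes``."""
        df = self._two_member_frame()
        pieces = {}
        for ph in phenotypes:
            wide = df.pivot_table(
                index="pair_id", columns="_order", values=ph, aggfunc="first"
            ).reindex(columns=[1, 2])
            pieces[f"{ph}_1"] = wide[1]
            pieces[f"{ph}_2"] = wide[2]
        out = pd.DataFrame(pieces)
        zyg = df.drop_duplicates("pair_id").set_index("pair_id")["zygosity"]
        out["zygosity"] = zyg.reindex(out.index)
        return out.dropna(subset=[c for c in out.columns if c != "zygosity"])

    def singleton_values(self, phenotype: str) -> np.ndarray:
        """Values for individuals whose co-twin is absent or phenotype-missing."""
        df = self.df.copy()
        df["_has"] = ~df[phenotype].isna()
        good = df[df["_has"]]
        counts = good.groupby("pair_id").size()
        single_ids = counts[counts == 1].index
        return good[good["pair_id"].isin(single_ids)][phenotype].to_numpy(float)

    def _two_member_frame(self) -> pd.DataFrame:
        df = self.df.sort_values(["pair_id", "person_id"]).copy()
        df["_order"] = df.groupby("pair_id").cumcount() + 1
        sizes = df.groupby("pair_id")["person_id"].transform("size")
        return df[sizes == 2]

    def with_values(self, column: str, values: np.ndarray) -> "TwinCohort":
        """Return a copy with ``column`` replaced (aligned to row order)."""
        df = self.df.copy()
        df[column] = np.asarray(values, float)
        return TwinCohort(df, dict(self.imputation_log))

    # -- i/o ----------------------------------------------------------
    def write_csv(self, path_or_buf) -> None:
        self.df[list(CANONICAL_COLUMNS)].to_csv(path_or_buf, index=False)

    def meta_json(self) -> str:
        return json.dumps(self.meta, indent=2)


def read_cohort(
    source,
    column_map: Mapping[str, str] | None = None,
    zygosity_codes: Mapping[str, str] | None = None,
    sex_codes: Mapping[str, str] | None = None,
) -> TwinCohort:
    """Read a cohort from a comma-separated, UTF-8 table with a header row.

    Empty fields are treated as missing.  ``column_map`` maps canonical
    column names to the file's column names; ``zygosity_codes`` /
    ``sex_codes`` map the file's codes onto {"MZ","DZ"} / {"male","female"}.

    Raises :class:`CohortError` for duplicated person ids, pairs with more
    than two members, or unknown zygosity/sex codes; malformed numeric
    fields are reported with their line number.
    """
    raw = pd.read_csv(source, dtype=str, keep_default_na=False)

    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in CANONICAL_COLUMNS}
    missing = [v for v in rename.values() if rename.get(column_map.get(v, v)) is None]
    present = {column_map.get(c, c) for c in CANONICAL_COLUMNS}
    absent = present - set(raw.columns)
    if absent:
        raise CohortError(f"missing column(s) in input: {sorted(absent)}")
    df = raw.rename(columns=rename)[list(CANONICAL_COLUMNS)].copy()

    if zygosity_codes:
        df["zygosity"] = df["zygosity"].map(lambda z: zygosity_codes.get(z, z))
    if sex_codes:
        df["sex"] = df["sex"].map(lambda s: sex_codes.get(s, s))

    bad_lines: list[str] = []
    for col in _NUMERIC_COLUMNS:
        vals = df[col].replace("", np.nan)
        parsed = pd.to_numeric(vals, errors="coerce")
        bad = vals.notna() & parsed.isna()
        for idx in df.index[bad]:
            # +2: header line and 1-based numbering
            bad_lines.append(f"line {idx + 2}: cannot parse {col}={df.at[idx, col]!r}")
        df[col] = parsed
    if bad_lines:
        raise CohortError("malformed rows:\n" + "\n".join(bad_lines))
    # raw BMI must be positive on ingest; analyses may later store
    # residualized (mean-zero) values in the same column
    bmi = df["bmi"].to_numpy(float)
    if np.any(bmi[~np.isnan(bmi)] <= 0):
        raise CohortError("non-positive BMI value(s) in input")
    return TwinCohort(df)


def write_cohort(cohort: TwinCohort, path_or_buf) -> None:
    """Write ``cohort`` in the canonical CSV dialect (empty string = missing)."""
    cohort.write_csv(path_or_buf)


def impute_covariates_median(cohort: TwinCohort) -> TwinCohort:
    """Replace missing covariate values by the column median.

    Phenotypes (BMI, walkability) are never imputed.  For binary 0/1
    covariates the median of the non-missing codes is used, so the filled
    value is again 0 or 1 (0.5 rounds up, matching the majority category in
    any non-tied column).  Returns a new cohort; the per-column imputation
    counts are recorded in ``imputation_log``.
    """
    df = cohort.df.copy()
    log: dict[str, int] = {}
    for col in COVARIATE_COLUMNS:
        vals = df[col]
        n_missing = int(vals.isna().sum())
        if n_missing == 0:
            log[col] = 0
            continue
        if vals.notna().sum() == 0:
            raise CohortError(f"covariate {col!r} is entirely missing; cannot impute")
        med = float(vals.median(skipna=True))
        if col in BINARY_COVARIATES:
            med = float(round(med))
        df[col] = vals.fillna(med)
        log[col] = n_missing
    out = TwinCohort(df, dict(cohort.imputation_log))
    out.imputation_log.update(log)
    return out


def residualize(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Least-squares residuals of ``values`` on ``covariates`` (with intercept).

    Rows with a missing value or covariate are excluded pairwise and remain
    NaN in the output, which is aligned to the input order.  The design must
    include (or will be given) an intercept column.  Residuals are orthogonal
    to every covariate column.

    Raises ``CohortError`` when the design is rank deficient, naming the
    collinear columns.
    """
    y = np.asarray(values, float)
    X = np.asarray(covariates, float)
    if X.ndim == 1:
        X = X[:, None]
    finite = X[~np.isnan(X).any(axis=1)]
    has_const = finite.size and np.any(
        (np.ptp(finite, axis=0) == 0) & (finite[0] != 0)
    )
    if not has_const:
        X = np.column_stack([np.ones(len(X)), X])
    ok = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    out = np.full_like(y, np.nan, dtype=float)
    Xo, yo = X[ok], y[ok]
    rank = np.linalg.matrix_rank(Xo)
    if rank < Xo.shape[1]:
        # identify columns linearly dependent on the preceding ones
        bad = []
        for j in range(1, Xo.shape[1]):
            if np.linalg.matrix_rank(Xo[:, : j + 1]) == np.linalg.matrix_rank(Xo[:, :j]):
                bad.append(j)
        raise CohortError(f"rank-deficient design: collinear column index(es) {bad}")
    beta, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    out[ok] = yo - Xo @ beta
    return out


def residualize_phenotype(
    cohort: TwinCohort,
    phenotype: str,
    covariate_names: Sequence[str] = ("age", "sex"),
) -> TwinCohort:
    """Return a cohort whose ``phenotype`` column is replaced by its residual
    on the named covariates (sex coded female=1)."""
    cols = []
    for name in covariate_names:
        if name == "sex":
            cols.append((cohort.df["sex"] == "female").to_numpy(float))
        else:
            cols.append(cohort.df[name].to_numpy(float))
    X = np.column_stack(cols) if cols else np.ones((len(cohort.df), 1))
    resid = residualize(cohort.df[phenotype].to_numpy(float), X)
    return cohort.with_values(phenotype, resid)
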