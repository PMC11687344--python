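"""Survey-data model, tabular I/O and construction of the detection array.

Long-format survey records (one row per species x site x year x survey) are
turned into the binary detection tensor V[i, j, k, l] that the occupancy
likelihood consumes, together with standardised covariates:

* per-survey day-of-year (one z-score standardiser across all observed
  surveys, so phenological peaks are comparable across years);
* per-survey total floral abundance, log1p-transformed then standardised;
* per site-year woody floral abundance: the mean over surveys of
  log1p(woody count), later standardised for modelling.

Surveys that were never conducted are masked, not imputed as non-detections.
Species never detected anywhere are unidentifiable under the model and are
excluded from the array (their names are reported).  Honey bees are managed,
not wild, and are dropped at parse time via a configurable species drop-list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurveyRecord",
    "SiteTable",
    "DetectionArray",
    "Standardizer",
    "read_survey_table",
    "read_site_table",
    "build_detection_array",
    "summarize_woody",
    "standardize",
    "save_bundle",
    "load_bundle",
    "DEFAULT_DROP_SPECIES",
]

DEFAULT_DROP_SPECIES = ("Apis_mellifera", "Apis mellifera")

_SURVEY_COLUMNS = [
    "species_id", "site_id", "year_index", "survey_index", "capture_count",
    "survey_date", "herbaceous_floral_count", "woody_floral_count",
]


@dataclass(frozen=True)
class SurveyRecord:
    """One species on one survey visit: the capture count plus the visit's
    date and floral context.  Indices are 1-based as stored in files."""

    species_id: str
    site_id: str
    year_index: int
    survey_index: int
    capture_count: int
    survey_date: int
    herbaceous_floral_count: int
    woody_floral_count: int

    def __post_init__(self) -> None:
        if self.capture_count < 0:
            raise ValueError("capture_count must be non-negative")
        if self.year_index < 1 or self.survey_index < 1:
            raise ValueError("year_index and survey_index are 1-based")
        if not 1 <= self.survey_date <= 366:
            raise ValueError("survey_date must be a day of year in 1..366")


@dataclass(frozen=True)
class SiteTable:
    """Per-site design information: the binary restoration flag and the
    per-year woody floral abundance summaries (log scale, pre-standardisation)."""

    site_ids: list[str]
    restored: np.ndarray                 # (n_sites,) in {0, 1}
    woody_by_year: np.ndarray            # (n_sites, n_years) log-scale means

    def __post_init__(self) -> None:
        if not np.isin(self.restored, (0, 1)).all():
            raise ValueError("restored must be binary 0/1")
        if self.woody_by_year.shape[0] != len(self.site_ids):
            raise ValueError("woody_by_year rows must match site_ids")


@dataclass(frozen=True)
class Standardizer:
    """A fitted z-score transform; invertible so covariate scenarios can be
    expressed on either scale."""

    mean: float
    sd: float

    def apply(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def invert(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


@dataclass
class DetectionArray:
    """Binary detection tensor V[i, j, k, l] plus the per-survey covariates the
    detection submodel needs.  ``mask`` is True where a survey was conducted
    (identical across species).  ``date_z`` and ``survey_flowers_z`` are
    standardised; their Standardizers are kept for scenario construction."""

    V: np.ndarray                        # (S, J, K, L) uint8
    mask: np.ndarray                     # (J, K, L) bool
    date_z: np.ndarray                   # (J, K, L) float, 0 where masked
    survey_flowers_z: np.ndarray         # (J, K, L) float, 0 where masked
    species_ids: list[str]
    site_ids: list[str]
    date_standardizer: Standardizer
    flowers_standardizer: Standardizer
    dropped_species: list[str] = field(default_factory=list)

    @property
    def n_species(self) -> int:
        return self.V.shape[0]

    @property
    def n_sites(self) -> int:
        return self.V.shape[1]

    @property
    def n_years(self) -> int:
        return self.V.shape[2]

    @property
    def n_surveys(self) -> int:
        return self.V.shape[3]


def read_survey_table(path, drop_species=DEFAULT_DROP_SPECIES) -> list[SurveyRecord]:
    """Parse a long-format survey CSV into records, dropping rows for species
    on the drop-list (by default the managed honey bee)."""
    df = pd.read_csv(path)
    missing = [c for c in _SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey table missing column(s): {', '.join(missing)}")
    for col in ("capture_count", "herbaceous_floral_count", "woody_floral_count"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValueError(f"negative {col} at row(s) {list(bad + 2)}")  # +2: header + 1-based
    if drop_species:
        df = df[~df["species_id"].isin(set(drop_species))]
    return [
        SurveyRecord(
            species_id=str(r.species_id), site_id=str(r.site_id),
            year_index=int(r.year_index), survey_index=int(r.survey_index),
            capture_count=int(r.capture_count), survey_date=int(r.survey_date),
            herbaceous_floral_count=int(r.herbaceous_floral_count),
            woody_floral_count=int(r.woody_floral_count),
        )
        for r in df.itertuples(index=False)
    ]


def _records_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def standardize(values) -> tuple[np.ndarray, Standardizer]:
    """Z-score standardise (population sd).  Binary design factors such as the
    restoration flag are left on their natural scale and must not be passed
    here; a constant vector is an error."""
    x = np.asarray(values, dtype=float)
    mean = float(x.mean())
    sd = float(x.std())
    if sd == 0.0:
        raise ValueError("cannot standardise a constant vector (sd = 0)")
    return (x - mean) / sd, Standardizer(mean=mean, sd=sd)


def summarize_woody(records) -> dict[tuple[str, int], float]:
    """Per site-year woody floral abundance: mean over surveys of
    log1p(woody_floral_count).

    Within a site-year-survey the woody count is a site-level measurement, so
    duplicated values across species rows collapse to one value per survey.
    """
    df = _records_frame(records)
    per_survey = (
        df.groupby(["site_id", "year_index", "survey_index"])["woody_floral_count"]
        .first()
    )
    out: dict[tuple[str, int], float] = {}
    for (site, year), grp in per_survey.groupby(level=["site_id", "year_index"]):
        if len(grp) == 0:
            raise ValueError(f"site-year ({site}, {year}) has zero surveys")
        out[(str(site), int(year))] = float(np.log1p(grp.to_numpy(dtype=float)).mean())
    return out


def site_table_from_records(records, n_years: int | None = None) -> SiteTable:
    """Derive the SiteTable woody summaries from survey records.  The restored
    flag cannot be derived from surveys and defaults to 0; use
    ``read_site_table`` or set it from design metadata."""
    woody = summarize_woody(records)
    sites = sorted({s for s, _ in woody})
    years = sorted({k for _, k in woody})
    if n_years is None:
        n_years = max(years)
    arr = np.zeros((len(sites), n_years))
    for (s, k), v in woody.items():
        arr[sites.index(s), k - 1] = v
    return SiteTable(site_ids=sites, restored=np.zeros(len(sites), dtype=int),
                     woody_by_year=arr)


def read_site_table(path) -> SiteTable:
    """Read sites.csv: site_id, restored, woody_year_1..woody_year_K."""
    df = pd.read_csv(path)
    if "site_id" not in df.columns or "restored" not in df.columns:
        raise ValueError("site table must have columns site_id, restored")
    woody_cols = sorted(
        [c for c in df.columns if c.startswith("woody_year_")],
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    if not woody_cols:
        raise ValueError("site table has no woody_year_<k> columns")
    return SiteTable(
        site_ids=list(df["site_id"].astype(str)),
        restored=df["restored"].to_numpy(dtype=int),
        woody_by_year=df[woody_cols].to_numpy(dtype=float),
    )


def write_site_table(table: SiteTable, path) -> None:
    df = pd.DataFrame({"site_id": table.site_ids, "restored": table.restored})
    for k in range(table.woody_by_year.shape[1]):
        df[f"woody_year_{k + 1}"] = table.woody_by_year[:, k]
    df.to_csv(path, index=False)


def build_detection_array(records, species_filter=None) -> DetectionArray:
    """Convert capture counts to the binary detection tensor.

    V[i,j,k,l] = 1 iff the species' capture count on that survey was positive.
    Site-year-survey cells with no record at all are masked.  Species with no
    detection anywhere are removed and listed in ``dropped_species``.
    """
    df = _records_frame(records)
    if species_filter is not None:
        df = df[df["species_id"].isin(set(species_filter))]
    if df.empty:
        raise ValueError("no survey records after filtering")

    dup = df.duplicated(["species_id", "site_id", "year_index", "survey_index"])
    if dup.any():
        keys = df.loc[dup, ["species_id", "site_id", "year_index", "survey_index"]]
        raise ValueError(
            "duplicate (species, site, year, survey) rows: "
            + "; ".join(map(str, keys.itertuples(index=False, name=None)))
        )

    species = sorted(df["species_id"].unique())
    sites = sorted(df["site_id"].unique())
    n_years = int(df["year_index"].max())
    n_surveys = int(df["survey_index"].max())
    s_ix = {s: i for i, s in enumerate(species)}
    j_ix = {s: j for j, s in enumerate(sites)}

    shape = (len(species), len(sites), n_years, n_surveys)
    V = np.zeros(shape, dtype=np.uint8)
    mask = np.zeros(shape[1:], dtype=bool)
    date = np.zeros(shape[1:])
    flowers = np.zeros(shape[1:])

    i = df["species_id"].map(s_ix).to_numpy()
    j = df["site_id"].map(j_ix).to_numpy()
    k = df["year_index"].to_numpy() - 1
    l = df["survey_index"].to_numpy() - 1
    V[i, j, k, l] = (df["capture_count"].to_numpy() > 0).astype(np.uint8)
    mask[j, k, l] = True
    date[j, k, l] = df["survey_date"].to_numpy(dtype=float)
    total = df["herbaceous_floral_count"].to_numpy(dtype=float) + \
        df["woody_floral_count"].to_numpy(dtype=float)
    flowers[j, k, l] = np.log1p(total)

    date_z = np.zeros_like(date)
    flowers_z = np.zeros_like(flowers)
    date_z[mask], date_std = standardize(date[mask])
    flowers_z[mask], flowers_std = standardize(flowers[mask])

    detected = V.reshape(len(species), -1).any(axis=1)
    dropped = [sp for sp, d in zip(species, detected) if not d]
    keep = np.flatnonzero(detected)

    return DetectionArray(
        V=V[keep], mask=mask, date_z=date_z, survey_flowers_z=flowers_z,
        species_ids=[species[ix] for ix in keep], site_ids=sites,
        date_standardizer=date_std, flowers_standardizer=flowers_std,
        dropped_species=dropped,
    )


def save_bundle(array: DetectionArray, path) -> None:
    """Serialise a DetectionArray to a self-describing .npz bundle."""
    np.savez(
        path,
        V=array.V, mask=array.mask, date_z=array.date_z,
        survey_flowers_z=array.survey_flowers_z,
        species_ids=np.array(array.species_ids),
        site_ids=np.array(array.site_ids),
        date_ms=np.array([array.date_standardizer.mean, array.date_standardizer.sd]),
        flowers_ms=np.array([array.flowers_standardizer.mean,
                             array.flowers_standardizer.sd]),
        dropped_species=np.array(array.dropped_species, dtype=object)
        if array.dropped_species else np.array([], dtype="U1"),
    )


def load_bundle(path) -> DetectionArray:
    with np.load(path, allow_pickle=True) as z:
        return DetectionArray(
            V=z["V"], mask=z["mask"], date_z=z["date_z"],
            survey_flowers_z=z["survey_flowers_z"],
            species_ids=[str(s) for s in z["species_ids"]],
            site_ids=[str(s) for s in z["site_ids"]],
            date_standardizer=Standardizer(*z["date_ms"]),
            flowers_standardizer=Standardizer(*z["flowers_ms"]),
            dropped_species=[str(s) for s in z["dropped_species"]],
        )
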