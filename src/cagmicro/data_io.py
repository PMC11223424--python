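"""Abundance-table and metadata I/O, normalization, rarefaction, and packaged fixtures.

The canonical on-disk layout is a UTF-8 TSV with taxa as rows and samples as
columns (the common amplicon convention); the transposed orientation is
readable via a flag. Relative abundances are kept on the fractional [0, 1]
scale internally; percentages appear only in printed reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("TT", "NT")
#: serum tumor markers carried in cohort metadata (units: CEA/AFP ng/ml, CA* U/ml)
MARKERS = ("CEA", "CA199", "CA125", "CA153", "AFP")

_REL_TOL = 1e-9


class DataError(ValueError):
    """Raised for malformed tables or metadata (duplicate ids, negatives, ...)."""


@dataclass(frozen=True)
class AbundanceTable:
    """A taxa × samples abundance matrix with a counts/relative flag.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are taxa, columns are samples, values non-negative.
    kind : str
        ``"counts"`` (integer sequence counts), ``"relative"`` (per-sample
        fractions summing to 1), or ``"fraction"`` (fractional scale but not
        unit-sum, e.g. a taxon subset or CAG profiles).
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative", "fraction"):
            raise DataError(f"unknown table kind {self.kind!r}")
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate taxon label(s): {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample id(s): {dups}")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise DataError("non-finite abundance values")
        if (values < 0).any():
            bad = df.index[np.argwhere(values < 0)[0][0]]
            raise DataError(f"negative abundance for taxon {bad!r}")
        if self.kind == "relative":
            sums = values.sum(axis=0)
            off = np.abs(sums - 1.0) > 1e-6
            if off.any():
                bad = df.columns[np.argmax(off)]
                raise DataError(
                    f"relative table column {bad!r} sums to {sums[np.argmax(off)]:.6g}, not 1"
                )

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def select_samples(self, sample_ids) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise DataError(f"unknown sample id(s): {missing}")
        return replace(self, data=self.data.loc[:, list(sample_ids)])

    def select_taxa(self, taxa) -> "AbundanceTable":
        missing = [t for t in taxa if t not in self.data.index]
        if missing:
            raise DataError(f"unknown taxon label(s): {missing}")
        sub = self.data.loc[list(taxa), :]
        # a taxon subset of a relative table no longer sums to 1
        kind = "counts" if self.kind == "counts" else "fraction"
        return AbundanceTable(sub, kind=kind)


def _infer_kind(df: pd.DataFrame) -> str:
    values = df.to_numpy(dtype=float)
    if np.allclose(values, np.round(values)) and values.max(initial=0) > 1.0:
        return "counts"
    if np.allclose(values.sum(axis=0), 1.0, atol=1e-6):
        return "relative"
    if np.allclose(values, np.round(values)):
        return "counts"
    raise DataError(
        "cannot infer table kind (neither integer counts nor unit-sum columns); "
        "pass kind explicitly"
    )


def read_abundance_table(
    path: str | Path,
    orientation: str = "taxa_rows",
    kind: str | None = None,
) -> AbundanceTable:
    """Read a TSV abundance table.

    ``orientation="taxa_rows"`` expects taxa as rows and samples as columns;
    ``"samples_rows"`` reads the transpose. ``kind`` overrides inference
    (integer body → counts; unit-sum columns → relative).
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise DataError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise DataError(f"cannot parse {path}: {exc}") from exc
    if orientation == "samples_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise DataError(f"non-numeric value in {path}: {exc}") from exc
    return AbundanceTable(df, kind=kind if kind is not None else _infer_kind(df))


def write_abundance_table(t: AbundanceTable, path: str | Path) -> None:
    t.data.to_csv(path, sep="\t", index_label="taxon")


def to_relative(t: AbundanceTable) -> AbundanceTable:
    """Convert a counts table to per-sample relative abundances (columns sum to 1)."""
    if t.kind != "counts":
        raise DataError("table is already relative; refusing double normalization")
    values = t.values()
    sums = values.sum(axis=0)
    if (sums <= 0).any():
        bad = t.data.columns[int(np.argmax(sums <= 0))]
        raise DataError(f"sample {bad!r} has zero total count")
    rel = values / sums
    return AbundanceTable(pd.DataFrame(rel, index=t.data.index, columns=t.data.columns),
                          kind="relative")


def rarefy(t: AbundanceTable, depth: int, seed: int | np.random.Generator) -> AbundanceTable:
    """Subsample every sample without replacement to a common depth.

    Samples whose total count is below ``depth`` are dropped (and logged),
    never up-sampled. Retained columns sum to exactly ``depth``. The marginal
    count of each taxon follows the multivariate hypergeometric distribution.
    """
    if t.kind != "counts":
        raise DataError("rarefaction requires a counts table")
    if depth <= 0:
        raise DataError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = t.values()
    if not np.allclose(values, np.round(values)):
        raise DataError("rarefaction requires integer counts")
    counts = np.round(values).astype(np.int64)
    totals = counts.sum(axis=0)
    keep = totals >= depth
    dropped = [s for s, k in zip(t.samples, keep) if not k]
    if dropped:
        logger.info("rarefy: dropping %d/%d samples below depth %d: %s",
                    len(dropped), len(t.samples), depth,
                    ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""))
    out = np.zeros((counts.shape[0], int(keep.sum())), dtype=np.int64)
    for j_out, j in enumerate(np.flatnonzero(keep)):
        if totals[j] == depth:
            out[:, j_out] = counts[:, j]
        else:
            out[:, j_out] = rng.multivariate_hypergeometric(counts[:, j], depth)
    cols = [s for s, k in zip(t.samples, keep) if k]
    return AbundanceTable(pd.DataFrame(out, index=t.data.index, columns=cols), kind="counts")


# ---------------------------------------------------------------------------
# sample metadata

METADATA_REQUIRED = ("patient_id", "tissue")


def validate_metadata(meta: pd.DataFrame, table: AbundanceTable | None = None) -> pd.DataFrame:
    """Validate a metadata frame indexed by sample id (patient_id + tissue required)."""
    if meta.index.duplicated().any():
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate sample id(s) in metadata: {dups}")
    for col in METADATA_REQUIRED:
        if col not in meta.columns:
            raise DataError(f"metadata missing required column {col!r}")
    bad = set(meta["tissue"].dropna().unique()) - set(TISSUES)
    if bad:
        raise DataError(f"unknown tissue label(s): {sorted(bad)}")
    if meta["tissue"].isna().any():
        raise DataError("tissue label missing for some samples")
    if table is not None:
        missing = [s for s in table.samples if s not in meta.index]
        if missing:
            raise DataError(f"samples absent from metadata: {missing[:5]}")
    return meta


def read_metadata(path: str | Path, table: AbundanceTable | None = None) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return validate_metadata(meta, table)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# packaged fixtures

@dataclass(frozen=True)
class CagMembershipFixture:
    """Published genus → CAG assignment (47 genera over CAG1..CAG4)."""

    assignment: dict[str, str] = field(repr=False)

    @property
    def cags(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def members(self, cag: str) -> list[str]:
        return [g for g, c in self.assignment.items() if c == cag]

    def sizes(self) -> dict[str, int]:
        return {c: len(self.members(c)) for c in self.cags}

    def __len__(self) -> int:
        return len(self.assignment)


def load_table2_fixture() -> CagMembershipFixture:
    """Load the packaged published CAG membership table (47 genera, 4 CAGs).

    The trailing "Unknown" entry of CAG1 is kept as a literal genus label, as
    published.
    """
    ref = resources.files("cagmicro").joinpath("data/cag_membership.tsv")
    df = pd.read_csv(ref.open("r", encoding="utf-8"), sep="\t")
    assignment = dict(zip(df["genus"].astype(str), df["cag"].astype(str)))
    if len(assignment) != len(df):
        raise DataError("duplicate genus in packaged CAG membership")
    return CagMembershipFixture(assignment)


def cohort_metadata_fixture() -> pd.DataFrame:
    """Synthetic per-sample cohort metadata matching the published Table-1 margins.

    The study deposits raw sequence reads but no per-sample metadata file, so
    this fixture is a deterministic synthetic reconstruction: 492 mucosal
    samples (245 tumor, 247 normal) from 248 colorectal-cancer patients
    (244 with both tissues, 1 tumor-only, 3 normal-only). Categorical
    variables reproduce the published patient-level counts exactly
    (e.g. microsatellite: 17 unstable / 230 stable / 1 missing); continuous
    variables are drawn once, with a fixed internal seed, at the published
    mean ± SD. Clinical values are patient-level and repeated on both samples
    of a patient.
    """
    rng = np.random.default_rng(20240703)
    n_pat = 248
    patients = [f"P{i + 1:03d}" for i in range(n_pat)]

    def categorical(counts: dict[str, int]) -> np.ndarray:
        vals = np.repeat(list(counts.keys()), list(counts.values()))
        assert len(vals) == n_pat
        return rng.permutation(vals)

    clin = pd.DataFrame(index=pd.Index(patients, name="patient_id"))
    clin["gender"] = categorical({"Female": 97, "Male": 151})
    clin["site"] = categorical({"Left hemicolon": 84, "Rectum": 109, "Right hemicolon": 55})
    clin["stage"] = categorical({"Advanced": 118, "Early": 130})
    clin["gross"] = categorical({"Infiltration": 2, "Mass": 67, "Ulcer": 177, "NA": 2})
    clin["differentiation"] = categorical({"High": 38, "Low": 179, "Median": 17, "NA": 14})
    clin["ki67"] = categorical({"50% or more": 127, "Less than 50%": 121})
    clin["microsatellite"] = categorical({"unstable": 17, "stable": 230, "NA": 1})
    clin = clin.replace("NA", pd.NA)

    clin["age"] = np.round(np.clip(rng.normal(62.94, 12.29, n_pat), 20, 95), 1)
    clin["bmi"] = np.round(np.clip(rng.normal(22.63, 3.27, n_pat), 14, 40), 1)
    # markers are heavily right-skewed in the published summary (SD >> mean);
    # lognormal shapes chosen once to land near the published mean
    for marker, (mu, sigma) in {
        "CEA": (1.2, 1.9), "CA199": (2.0, 1.7), "CA125": (2.4, 0.9),
        "CA153": (2.2, 0.5), "AFP": (0.9, 0.7),
    }.items():
        vals = np.round(rng.lognormal(mu, sigma, n_pat), 2)
        vals[rng.random(n_pat) < 0.01] = np.nan  # sporadic missing assays
        clin[marker] = vals

    # 245 TT + 247 NT: patients 1..244 paired, P245 tumor-only, P246-248 normal-only
    rows = []
    for i, pid in enumerate(patients):
        tissues = ["TT", "NT"]
        if i == 244:
            tissues = ["TT"]
        elif i >= 245:
            tissues = ["NT"]
        for tis in tissues:
            rows.append({"sample_id": f"{pid}_{tis}", "patient_id": pid, "tissue": tis,
                         **clin.loc[pid].to_dict()})
    meta = pd.DataFrame(rows).set_index("sample_id")
    return validate_metadata(meta)
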