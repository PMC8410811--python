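"""Heavy-metal pollution and ecological-risk indices for mine drainage.

Implements the classical index battery used to grade metal-laden effluent
against background (pristine) water: the contamination factor CF = C/B and
its aggregates (pollution load index, Nemerow pollution index, degree of
contamination), the enrichment factor EF, Müller's geo-accumulation index
I_geo = log2(CF / 1.5), Hakanson's potential ecological risk factors
Er = Tr * CF and their sum RI, the "modified" variants built on EF, and the
risk quotient RQ = MEC / PNEC.

Indices are computed per replicate and then averaged (mean ± SEM), which is
the convention triplicate field studies report; note that for nonlinear
indices (I_geo, PLI) this differs from computing the index on the mean
concentrations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import ConfigurationError, ReferenceDataError, SchemeCoverageError

__all__ = [
    "Band",
    "ClassificationScheme",
    "ReferenceSet",
    "HAKANSON_TR",
    "default_scheme",
    "contamination_factor",
    "enrichment_factor",
    "geoaccumulation_index",
    "pollution_load_index",
    "nemerow_pollution_index",
    "degree_of_contamination",
    "modified_pollution_index",
    "ecological_risk_factor",
    "risk_index",
    "risk_quotient",
    "classify_index",
    "PollutionRiskAssessor",
    "assess",
]

# Hakanson toxic-response factors; Fe carries no canonical factor and is
# conventionally given unit weight.
HAKANSON_TR: dict[str, float] = {
    "Cd": 30.0, "As": 10.0, "Pb": 5.0, "Ni": 5.0, "Co": 5.0, "Cr": 2.0,
    "Cu": 5.0, "Zn": 1.0, "Hg": 40.0, "Fe": 1.0,
}


@dataclass(frozen=True)
class Band:
    """One classification interval with explicit bound closure.

    ``closed`` is one of ``"left"``, ``"right"``, ``"both"``, ``"neither"``.
    """

    lower: float
    upper: float
    label: str
    closed: str = "left"

    def contains(self, value: float) -> bool:
        lo_ok = value >= self.lower if self.closed in ("left", "both") else value > self.lower
        hi_ok = value <= self.upper if self.closed in ("right", "both") else value < self.upper
        return lo_ok and hi_ok


@dataclass
class ClassificationScheme:
    """Ordered interval → label maps, one per index name."""

    bands: dict[str, list[Band]] = field(default_factory=dict)

    def classify(self, index_name: str, value: float) -> str:
        if index_name not in self.bands:
            raise SchemeCoverageError(f"no classification bands defined for index {index_name!r}")
        hits = [b.label for b in self.bands[index_name] if b.contains(value)]
        if len(hits) != 1:
            raise SchemeCoverageError(
                f"{index_name}={value!r} matched {len(hits)} bands; scheme must assign exactly one label"
            )
        return hits[0]


def default_scheme() -> ClassificationScheme:
    """Interpretation bins for every index, following the inequality
    conventions customary for each index family (Hakanson CF/Er/C_d, Müller
    I_geo, Nemerow PI, Sutherland-style EF).  Where a family's published
    grading stops at a single threshold, the open side keeps a "below
    <label> threshold" label so the scheme covers all non-negative values.
    """
    inf = math.inf
    return ClassificationScheme(bands={
        "CF": [
            Band(0, 1, "low"),
            Band(1, 3, "moderate"),
            Band(3, 6, "considerable", closed="both"),
            Band(6, inf, "very high", closed="neither"),
        ],
        "EF": [
            Band(0, 3, "minimal"),
            Band(3, 5, "moderate"),
            Band(5, 25, "high"),
            Band(25, 50, "very high"),
            Band(50, inf, "exceptionally high"),
        ],
        "Igeo": [
            Band(-inf, 0, "unpolluted", closed="right"),
            Band(0, 1, "unpolluted to moderate", closed="right"),
            Band(1, 2, "moderate", closed="right"),
            Band(2, 3, "moderate to severe", closed="right"),
            Band(3, 4, "severe", closed="right"),
            Band(4, 5, "severe to very severe", closed="neither"),
            Band(5, inf, "very severe"),
        ],
        "PLI": [
            Band(0, 100, "below progressively deteriorating threshold", closed="both"),
            Band(100, inf, "progressively deteriorating", closed="neither"),
        ],
        "PI": [
            Band(0, 0.7, "clean", closed="both"),
            Band(0.7, 1, "warning", closed="right"),
            Band(1, 2, "slight", closed="right"),
            Band(2, 3, "moderate", closed="right"),
            Band(3, inf, "severe", closed="neither"),
        ],
        "MPI": [
            Band(0, 1, "unpolluted"),
            Band(1, 2, "slight"),
            Band(2, 3, "moderate"),
            Band(3, 5, "moderately heavy"),
            Band(5, 10, "heavy", closed="both"),
            Band(10, inf, "severe", closed="neither"),
        ],
        "Cd_deg": [
            Band(0, 8, "low"),
            Band(8, 16, "moderate"),
            Band(16, 32, "considerable"),
            Band(32, inf, "severe"),
        ],
        "MCd": [
            Band(0, 1.5, "nil to very low"),
            Band(1.5, 2, "low"),
            Band(2, 4, "moderate"),
            Band(4, 8, "high"),
            Band(8, 16, "very high"),
            Band(16, 32, "extremely high"),
            Band(32, inf, "severe"),
        ],
        "Er": [
            Band(0, 40, "low"),
            Band(40, 80, "moderate"),
            Band(80, 160, "considerable"),
            Band(160, 320, "high", closed="both"),
            Band(320, inf, "very high", closed="neither"),
        ],
        "MEr": [
            Band(0, 40, "low"),
            Band(40, 80, "moderate", closed="both"),
            Band(80, 160, "considerate", closed="right"),
            Band(160, 320, "high", closed="right"),
            Band(320, inf, "very high", closed="neither"),
        ],
        "RQ": [
            Band(0, 0.1, "low"),
            Band(0.1, 1, "moderate", closed="both"),
            Band(1, inf, "high", closed="neither"),
        ],
        "RI": [
            Band(0, 320, "below very high threshold", closed="both"),
            Band(320, inf, "very high", closed="neither"),
        ],
        "MRI": [
            Band(0, 320, "below very high threshold", closed="both"),
            Band(320, inf, "very high", closed="neither"),
        ],
    })


@dataclass
class ReferenceSet:
    """Background concentrations and toxicity weights for a set of analytes.

    Parameters
    ----------
    background : dict
        Analyte -> background concentration B (mg/L) from an uncontaminated
        reference site.  Must be > 0 for every analyte assessed.
    tr : dict, optional
        Analyte -> toxic-response factor (dimensionless).  Defaults to the
        Hakanson weights for analytes that have one.
    pnec : dict, optional
        Analyte -> predicted-no-effect concentration (mg/L) for RQ.
    reference_element : str, optional
        Conservative element used to double-normalise the enrichment factor.
        When absent, EF falls back to CF and the report records the variant.
    """

    background: dict[str, float]
    tr: dict[str, float] = field(default_factory=lambda: dict(HAKANSON_TR))
    pnec: dict[str, float] = field(default_factory=dict)
    reference_element: str | None = None

    def __post_init__(self) -> None:
        for analyte, b in self.background.items():
            if not b > 0:
                raise ReferenceDataError(
                    f"background concentration for {analyte!r} must be > 0, got {b!r}"
                )


# ---------------------------------------------------------------------------
# elemental index functions
# ---------------------------------------------------------------------------

def contamination_factor(concentration: float, background: float, *, analyte: str = "?") -> float:
    """CF = C / B."""
    if not background > 0:
        raise ReferenceDataError(
            f"background concentration for {analyte!r} must be > 0, got {background!r}"
        )
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration!r}")
    return concentration / background


def enrichment_factor(
    concentration: float,
    reference_concentration: float | None,
    background: float,
    reference_background: float | None,
    *,
    analyte: str = "?",
) -> float:
    """EF = (C_M / C_ref) / (B_M / B_ref).

    With no reference element configured (both reference terms ``None``),
    EF degenerates to CF; callers record that variant in their report.
    """
    if reference_concentration is None and reference_background is None:
        return contamination_factor(concentration, background, analyte=analyte)
    if reference_concentration is None or reference_background is None:
        raise ConfigurationError(
            f"enrichment factor for {analyte!r} needs both the sample and background "
            "concentrations of the reference element"
        )
    for name, v in (("reference sample concentration", reference_concentration),
                    ("background", background),
                    ("reference background", reference_background)):
        if not v > 0:
            raise ReferenceDataError(f"{name} for {analyte!r} must be > 0, got {v!r}")
    return (concentration / reference_concentration) / (background / reference_background)


def geoaccumulation_index(concentration: float, background: float, *, analyte: str = "?") -> float:
    """I_geo = log2(C / (1.5 B)); NaN for a zero concentration (undefined,
    reported as missing rather than -inf)."""
    cf = contamination_factor(concentration, background, analyte=analyte)
    if cf == 0:
        return math.nan
    return math.log2(cf / 1.5)


def ecological_risk_factor(tr: float, factor: float, *, analyte: str = "?") -> float:
    """Er = Tr * CF (or MEr = Tr * EF when fed an enrichment factor)."""
    if tr is None or not tr > 0:
        raise ReferenceDataError(f"toxic-response factor for {analyte!r} must be > 0, got {tr!r}")
    return tr * factor

def risk_quotient(mec: float, pnec: float, *, analyte: str = "?") -> float:
    """RQ = MEC / PNEC."""
    if pnec is None or math.isnan(pnec):
        warnings.warn(f"no PNEC for {analyte!r}; RQ reported as missing", stacklevel=2)
        return math.nan
    if not pnec > 0:
        raise ReferenceDataError(f"PNEC for {analyte!r} must be > 0, got {pnec!r}")
    return mec / pnec


# ---------------------------------------------------------------------------
# aggregate indices
# ---------------------------------------------------------------------------

def _as_clean_array(values, name: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} requires a non-empty list of factors")
    return arr


def pollution_load_index(cfs) -> float:
    """PLI = geometric mean of the contamination factors."""
    arr = _as_clean_array(cfs, "pollution_load_index")
    if np.any(arr <= 0):
        raise ValueError("pollution_load_index requires all CF > 0")
    return float(np.exp(np.mean(np.log(arr))))


def nemerow_pollution_index(cfs) -> float:
    """PI = sqrt((CF_max^2 + CF_mean^2) / 2)."""
    arr = _as_clean_array(cfs, "nemerow_pollution_index")
    if np.any(arr < 0):
        raise ValueError("nemerow_pollution_index requires all CF >= 0")
    return float(math.sqrt((arr.max() ** 2 + arr.mean() ** 2) / 2.0))


def modified_pollution_index(efs) -> float:
    """Nemerow composite over enrichment factors: sqrt((EF_max^2 + EF_mean^2)/2)."""
    return nemerow_pollution_index(efs)


def degree_of_contamination(cfs, *, mcd_variant: str = "mean_cf") -> tuple[float, float]:
    """C_d = sum(CF); MC_d defaults to C_d / n (``mcd_variant='mean_cf'``)."""
    arr = _as_clean_array(cfs, "degree_of_contamination")
    cd = float(arr.sum())
    if mcd_variant == "mean_cf":
        mcd = cd / arr.size
    else:
        raise ConfigurationError(f"unknown MC_d variant {mcd_variant!r}")
    return cd, mcd


def risk_index(factors) -> float:
    """RI = sum of per-metal ecological risk factors (MRI when fed MEr)."""
    return float(_as_clean_array(factors, "risk_index").sum())


def classify_index(value: float, index_name: str, scheme: ClassificationScheme | None = None) -> str:
    """Return the unique interpretation label for ``value`` under ``scheme``."""
    scheme = scheme if scheme is not None else default_scheme()
    return scheme.classify(index_name, value)


# ---------------------------------------------------------------------------
# full-table assessment
# ---------------------------------------------------------------------------

_PER_METAL = ["CF", "EF", "Igeo", "Er", "MEr", "RQ"]
_AGGREGATES = ["PLI", "PI", "MPI", "Cd_deg", "MCd", "RI", "MRI"]

_REQUIRED_COLUMNS = ["sample_id", "replicate_id", "analyte", "concentration_mg_per_L"]


class PollutionRiskAssessor(BaseEstimator):
    """Fit the full pollution/ecological-risk index battery on a long-format
    concentration table.

    Parameters
    ----------
    references : ReferenceSet
        Backgrounds, toxic-response factors and optional PNECs.
    scheme : ClassificationScheme, optional
        Interpretation bins; defaults to :func:`default_scheme`.
    mcd_variant : str, default "mean_cf"
        Formula variant for the modified degree of contamination.
    mpi_basis : {"ef", "cf"}, default "ef"
        Factors fed to the Nemerow-style modified pollution index.
    mer_basis : {"ef", "cf"}, default "ef"
        Factors multiplied by Tr to form the modified risk factor MEr.

    Attributes
    ----------
    per_metal_ : pandas.DataFrame
        Per (sample, analyte): mean, SEM and class label of each per-metal
        index, aggregated across replicates.
    aggregates_ : pandas.DataFrame
        Per sample: mean, SEM and class label of each aggregate index
        (aggregates are computed within each replicate, then averaged).
    variants_ : dict
        Formula variants actually used, stamped for provenance.
    n_replicates_ : pandas.Series
        Replicate count per sample.
    """

    def __init__(
        self,
        references: ReferenceSet | None = None,
        scheme: ClassificationScheme | None = None,
        mcd_variant: str = "mean_cf",
        mpi_basis: str = "ef",
        mer_basis: str = "ef",
    ):
        self.references = references
        self.scheme = scheme
        self.mcd_variant = mcd_variant
        self.mpi_basis = mpi_basis
        self.mer_basis = mer_basis

    # -- helpers -----------------------------------------------------------
    def _validate_table(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in _REQUIRED_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"concentration table is missing columns {missing}")
        X = X.copy()
        X["concentration_mg_per_L"] = pd.to_numeric(X["concentration_mg_per_L"])
        if (X["concentration_mg_per_L"].dropna() < 0).any():
            raise ValueError("concentrations must be >= 0")
        dup = X.duplicated(subset=["sample_id", "replicate_id", "analyte"])
        if dup.any():
            raise ValueError(
                f"duplicate (sample, replicate, analyte) rows: {X.loc[dup].head().to_dict('records')}"
            )
        refs = self.references
        if refs is None:
            raise ConfigurationError("PollutionRiskAssessor requires a ReferenceSet")
        absent = sorted(set(X["analyte"]) - set(refs.background))
        if absent:
            raise ReferenceDataError(f"no background concentration for analytes {absent}")
        return X

    def _replicate_indices(self, rep: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
        """Index values for one replicate of one sample."""
        refs = self.references
        conc = dict(zip(rep["analyte"], rep["concentration_mg_per_L"]))
        ref_el = refs.reference_element
        if ref_el is not None and ref_el not in conc:
            raise ConfigurationError(
                f"reference element {ref_el!r} has no measured concentration in this replicate"
            )
        rows = {}
        for analyte, c in conc.items():
            if np.isnan(c):
                # below-detection / missing: propagate as missing, never zero
                rows[analyte] = {k: math.nan for k in _PER_METAL}
                continue
            b = refs.background[analyte]
            cf = contamination_factor(c, b, analyte=analyte)
            if ref_el is None:
                ef = cf
            else:
                ef = enrichment_factor(
                    c, conc[ref_el], b, refs.background[ref_el], analyte=analyte
                )
            igeo = geoaccumulation_index(c, b, analyte=analyte)
            tr = refs.tr.get(analyte)
            er = ecological_risk_factor(tr, cf, analyte=analyte) if tr else math.nan
            basis = ef if self.mer_basis == "ef" else cf
            mer = ecological_risk_factor(tr, basis, analyte=analyte) if tr else math.nan
            if analyte in refs.pnec:
                rq = risk_quotient(c, refs.pnec[analyte], analyte=analyte)
            else:
                rq = math.nan
            rows[analyte] = {"CF": cf, "EF": ef, "Igeo": igeo, "Er": er, "MEr": mer, "RQ": rq}
        per_metal = pd.DataFrame.from_dict(rows, orient="index")

        cfs = per_metal["CF"].dropna()
        efs = per_metal["EF"].dropna()
        ers = per_metal["Er"].dropna()
        mers = per_metal["MEr"].dropna()
        cd, mcd = degree_of_contamination(cfs, mcd_variant=self.mcd_variant)
        mpi_src = efs if self.mpi_basis == "ef" else cfs
        agg = {
            "PLI": pollution_load_index(cfs[cfs > 0]) if (cfs > 0).any() else math.nan,
            "PI": nemerow_pollution_index(cfs),
            "MPI": modified_pollution_index(mpi_src),
            "Cd_deg": cd,
            "MCd": mcd,
            "RI": risk_index(ers) if len(ers) else math.nan,
            "MRI": risk_index(mers) if len(mers) else math.nan,
        }
        return per_metal, agg

    @staticmethod
    def _mean_sem(frame: pd.DataFrame) -> pd.DataFrame:
        """Mean and SEM over replicates; SEM is NaN for a single replicate."""
        mean = frame.mean()
        n = frame.notna().sum()
        sem = frame.std(ddof=1) / np.sqrt(n)
        sem[n <= 1] = math.nan
        return pd.DataFrame({"mean": mean, "sem": sem})

    # -- estimator API -----------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None):
        """Compute all indices from a long concentration table.

        ``X`` columns: sample_id, replicate_id, analyte, concentration_mg_per_L.
        """
        X = self._validate_table(X)
        scheme = self.scheme if self.scheme is not None else default_scheme()

        per_metal_rows = []
        agg_rows = []
        n_reps = {}
        for sample_id, sample in X.groupby("sample_id", sort=True):
            reps = list(sample.groupby("replicate_id", sort=True))
            n_reps[sample_id] = len(reps)
            metal_frames = []
            agg_records = []
            for rep_id, rep in reps:
                pm, agg = self._replicate_indices(rep)
                metal_frames.append(pm)
                agg_records.append(agg)
            stacked = pd.concat(metal_frames, keys=range(len(metal_frames)))
            for analyte in sorted({a for f in metal_frames for a in f.index}):
                vals = stacked.xs(analyte, level=1)
                ms = self._mean_sem(vals)
                row = {"sample_id": sample_id, "analyte": analyte}
                for ix in _PER_METAL:
                    m, s = ms.loc[ix, "mean"], ms.loc[ix, "sem"]
                    row[f"{ix}_mean"] = m
                    row[f"{ix}_sem"] = s
                    row[f"{ix}_class"] = scheme.classify(ix, m) if not np.isnan(m) else None
                per_metal_rows.append(row)
            agg_frame = pd.DataFrame(agg_records)
            ms = self._mean_sem(agg_frame)
            row = {"sample_id": sample_id}
            for ix in _AGGREGATES:
                m, s = ms.loc[ix, "mean"], ms.loc[ix, "sem"]
                row[f"{ix}_mean"] = m
                row[f"{ix}_sem"] = s
                row[f"{ix}_class"] = scheme.classify(ix, m) if not np.isnan(m) else None
            agg_rows.append(row)

        self.per_metal_ = pd.DataFrame(per_metal_rows).set_index(["sample_id", "analyte"])
        self.aggregates_ = pd.DataFrame(agg_rows).set_index("sample_id")
        self.n_replicates_ = pd.Series(n_reps, name="n_replicates")
        self.variants_ = {
            "EF": "CF fallback (no reference element)"
            if self.references.reference_element is None
            else f"double-normalised to {self.references.reference_element}",
            "MCd": self.mcd_variant,
            "MPI": f"nemerow over {self.mpi_basis.upper()}",
            "MEr": f"Tr x {self.mer_basis.upper()}",
            "RQ": "MEC / PNEC",
            "replicates": "indices per replicate, then mean +/- SEM",
        }
        return self


def assess(
    table: pd.DataFrame,
    references: ReferenceSet,
    scheme: ClassificationScheme | None = None,
    **variants,
) -> PollutionRiskAssessor:
    """Functional wrapper: fit a :class:`PollutionRiskAssessor` and return it."""
    return PollutionRiskAssessor(references=references, scheme=scheme, **variants).fit(table)
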