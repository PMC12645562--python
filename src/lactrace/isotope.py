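"""Natural-abundance correction of mass isotopologue distributions and tracer statistics.

Mass-shift indexing is 0-based throughout: index 0 is m+0, index k is m+k.

A measured mass isotopologue distribution (MID) of an n-carbon metabolite mixes
the tracer-derived labelling signal with naturally occurring ``13C`` (~1.1% of all
carbon). This module builds the binomial forward model mapping true tracer-label
fractions to observed mass-shift fractions, inverts it by non-negative least
squares, and computes the three tracer statistics used downstream:

* molecular ``13C`` enrichment ``E`` — the mean fraction of a metabolite's carbons
  that are ``13C``,
* the normalized (contribution) ratio ``E_metabolite / E_lactate`` within the same
  sample and compartment,
* the pyruvate-cycling proxy ``(m+1 + m+2) / m+3`` for three-carbon metabolites.

Correction is carbon-only: on a high-resolution Orbitrap-class instrument the
isotopic contributions of O/H/N are mass-resolved away, so only ``13C`` abundance
and tracer purity enter the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import binom

#: consensus natural abundance of 13C (fraction of all carbon atoms)
DEFAULT_P13 = 0.01109
#: default isotopic purity of the tracer's labelled positions
DEFAULT_TRACER_PURITY = 0.99

#: reason codes attached to undefined / excluded records
REASON_ZERO_TRACER = "zero_tracer_enrichment"
REASON_ZERO_M3 = "zero_m3_fraction"
REASON_MISSING_TRACER = "missing_tracer_row"


class ParameterError(ValueError):
    """Invalid model or call parameters."""


class DataError(ValueError):
    """Input data violate a precondition (all-zero vector, bad dimensions...)."""


class PairingError(DataError):
    """A sample lacks the tracer-metabolite row needed for normalization."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class IsotopologueVector:
    """MID (or raw intensity vector) for one metabolite in one sample.

    ``values[k]`` is the intensity or fraction of the m+k species,
    k = 0 ... n_carbons.
    """

    metabolite: str
    n_carbons: int
    values: np.ndarray
    is_fraction: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_carbons < 1 or int(self.n_carbons) != self.n_carbons:
            raise ParameterError(f"n_carbons must be a positive integer, got {self.n_carbons}")
        if self.values.shape != (self.n_carbons + 1,):
            raise ParameterError(
                f"{self.metabolite}: expected {self.n_carbons + 1} values "
                f"(m+0..m+{self.n_carbons}), got {self.values.shape}"
            )
        if np.any(self.values < -1e-12):
            raise DataError(f"{self.metabolite}: negative isotopologue values")
        if self.is_fraction and abs(self.values.sum() - 1.0) > 1e-9:
            raise DataError(
                f"{self.metabolite}: fraction vector sums to {self.values.sum():.12f}, not 1"
            )


@dataclass
class CorrectionModel:
    """Forward model of natural abundance (and tracer impurity) for one carbon count.

    ``matrix[i, j]`` = P(observed mass shift i | j tracer-labelled carbons).
    Each tracer-labelled carbon is truly ``13C`` with probability
    ``tracer_purity``; each of the remaining ``n_carbons - j`` carbons is
    naturally ``13C`` with probability ``p13``. Columns are probability
    distributions and sum to 1. With ``tracer_purity == 1`` the matrix is lower
    triangular (natural abundance can only add mass).
    """

    n_carbons: int
    p13: float = DEFAULT_P13
    tracer_purity: float = DEFAULT_TRACER_PURITY
    matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_carbons < 1 or int(self.n_carbons) != self.n_carbons:
            raise ParameterError(f"n_carbons must be a positive integer, got {self.n_carbons}")
        if not 0.0 <= self.p13 < 0.5:
            raise ParameterError(f"p13 must lie in [0, 0.5), got {self.p13}")
        if not 0.0 < self.tracer_purity <= 1.0:
            raise ParameterError(f"tracer_purity must lie in (0, 1], got {self.tracer_purity}")
        self.matrix = self._build_matrix()

    def _build_matrix(self) -> np.ndarray:
        n = self.n_carbons
        m = np.zeros((n + 1, n + 1))
        shifts = np.arange(n + 1)
        for j in range(n + 1):
            # retained tracer label ~ Binomial(j, purity); natural gains on the
            # n-j unlabelled positions ~ Binomial(n-j, p13); observed shift is
            # their (independent) sum.
            retained = binom.pmf(np.arange(j + 1), j, self.tracer_purity)
            natural = binom.pmf(np.arange(n - j + 1), n - j, self.p13)
            col = np.convolve(retained, natural)
            m[shifts, j] = col
        return m

    def forward(self, fractions: np.ndarray) -> np.ndarray:
        """Convolve true label fractions into observed mass-shift fractions."""
        x = np.asarray(fractions, dtype=float)
        if x.shape != (self.n_carbons + 1,):
            raise ParameterError(
                f"fraction vector length {x.shape} does not match n_carbons={self.n_carbons}"
            )
        return self.matrix @ x


@dataclass
class EnrichmentRecord:
    """Per-sample, per-metabolite tracer statistics.

    Undefined ratios are NaN with the reason recorded in ``flags`` — never
    silently 0 or infinity.
    """

    sample_id: str
    group: str
    tissue: str
    metabolite: str
    n_carbons: int
    molecular_enrichment: float
    normalized_ratio: float = math.nan
    cycling_ratio: float = math.nan
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_correction_matrix(
    n_carbons: int,
    p13: float = DEFAULT_P13,
    tracer_purity: float = DEFAULT_TRACER_PURITY,
) -> CorrectionModel:
    """Build the natural-abundance forward model for a metabolite with ``n_carbons``."""
    return CorrectionModel(n_carbons=n_carbons, p13=p13, tracer_purity=tracer_purity)


def correct_mid(raw: IsotopologueVector, model: CorrectionModel) -> IsotopologueVector:
    """Remove natural abundance (and impurity) from a measured MID.

    Solves ``min ||M x - y||_2`` subject to ``x >= 0`` where ``y`` is the
    normalized raw vector, then renormalizes ``x`` to sum 1. Exact inversion
    is recovered whenever the raw vector was generated by the forward model
    from a valid fraction vector; on noisy data the non-negativity constraint
    prevents the negative fractions a plain matrix inverse would produce.
    """
    if raw.n_carbons != model.n_carbons:
        raise ParameterError(
            f"{raw.metabolite}: vector has {raw.n_carbons} carbons, model {model.n_carbons}"
        )
    total = raw.values.sum()
    if total <= 0:
        raise DataError(f"{raw.metabolite}: all-zero raw vector cannot be corrected")
    y = raw.values / total
    x, _ = nnls(model.matrix, y)
    s = x.sum()
    if s <= 0:  # pragma: no cover - nnls returns 0 only for y == 0
        raise DataError(f"{raw.metabolite}: correction produced an empty vector")
    return IsotopologueVector(
        metabolite=raw.metabolite,
        n_carbons=raw.n_carbons,
        values=x / s,
        is_fraction=True,
    )


def molecular_enrichment(corrected: IsotopologueVector) -> float:
    """Molecular ``13C`` enrichment: mean labelled fraction of the carbon skeleton.

    ``E = sum_k k * x_k / n_carbons``, in [0, 1] — the MID weighted by the
    number of ``13C`` atoms in each isotopologue, divided by the carbon count.
    """
    if not corrected.is_fraction:
        raise DataError(
            f"{corrected.metabolite}: molecular enrichment requires fractions, not intensities"
        )
    k = np.arange(corrected.n_carbons + 1)
    return float(k @ corrected.values / corrected.n_carbons)


def normalized_enrichment(metabolite_e: float, lactate_e: float) -> float:
    """Tracer contribution ratio: metabolite enrichment over tracer (lactate) enrichment.

    Both enrichments must come from the same sample and compartment (enforced
    by sample-id matching upstream). A zero tracer enrichment makes the ratio
    undefined and must be handled by the caller via the raised error.
    """
    if lactate_e == 0:
        raise DataError(REASON_ZERO_TRACER)
    if not (0 <= metabolite_e <= 1 and 0 < lactate_e <= 1):
        raise ParameterError("enrichments must be fractions in [0, 1]")
    return metabolite_e / lactate_e


def cycling_ratio(corrected: IsotopologueVector) -> float:
    """Pyruvate-cycling proxy ``(m+1 + m+2) / m+3`` for a 3-carbon metabolite.

    The higher the ratio, the more of the [U-13C] label has passed through a
    decarboxylating recycle (pyruvate carboxylase -> TCA four-carbon pool ->
    PEPCK+pyruvate kinase or malic enzyme) that strips ``13C`` atoms from the
    initially triply-labelled species.
    """
    if corrected.n_carbons != 3:
        raise ParameterError(
            f"cycling ratio is defined for 3-carbon metabolites, got n={corrected.n_carbons}"
        )
    if not corrected.is_fraction:
        raise DataError(f"{corrected.metabolite}: cycling ratio requires fractions")
    x = corrected.values
    if x[3] == 0:
        raise DataError(REASON_ZERO_M3)
    return float((x[1] + x[2]) / x[3])


# ---------------------------------------------------------------------------
# Table-level driver (mids.csv dialect)
# ---------------------------------------------------------------------------

MID_ID_COLUMNS = ["sample_id", "group", "tissue", "metabolite", "n_carbons"]


def mid_columns(n_carbons: int) -> list[str]:
    return [f"m{k}" for k in range(n_carbons + 1)]


def table_to_vectors(table: pd.DataFrame) -> list[tuple[pd.Series, IsotopologueVector]]:
    """Parse a mids-table DataFrame into (row metadata, IsotopologueVector) pairs.

    Expected columns: sample_id, group, tissue, metabolite, n_carbons, m0...mN
    with ragged tails left empty for metabolites with fewer carbons.
    """
    missing = [c for c in MID_ID_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"mids table lacks required columns: {missing}")
    out = []
    for _, row in table.iterrows():
        n = int(row["n_carbons"])
        cols = mid_columns(n)
        absent = [c for c in cols if c not in table.columns]
        if absent:
            raise DataError(f"mids table lacks isotopologue columns {absent} for n={n}")
        values = row[cols].to_numpy(dtype=float)
        if np.any(np.isnan(values)):
            raise DataError(
                f"{row['sample_id']}/{row['metabolite']}: missing isotopologue intensities"
            )
        vec = IsotopologueVector(metabolite=str(row["metabolite"]), n_carbons=n, values=values)
        out.append((row, vec))
    return out


def process_mid_table(
    table: pd.DataFrame,
    p13: float = DEFAULT_P13,
    tracer_purity: float = DEFAULT_TRACER_PURITY,
    tracer_metabolite: str = "lactate",
) -> pd.DataFrame:
    """Correct every MID in a cohort table and compute all tracer statistics.

    Normalization pairs each metabolite with the tracer metabolite of the same
    sample_id *and* tissue (plasma metabolites normalize to plasma lactate,
    tissue metabolites to the same tissue's lactate). Returns a tidy DataFrame
    of EnrichmentRecord fields plus the corrected fractions; undefined ratios
    are NaN with a reason code in ``flags``.
    """
    rows = table_to_vectors(table)
    models: dict[int, CorrectionModel] = {}
    corrected: list[tuple[pd.Series, IsotopologueVector]] = []
    for meta, vec in rows:
        model = models.setdefault(
            vec.n_carbons, build_correction_matrix(vec.n_carbons, p13, tracer_purity)
        )
        corrected.append((meta, correct_mid(vec, model)))

    # tracer enrichment per (sample, tissue) compartment
    tracer_e: dict[tuple[str, str], float] = {}
    for meta, vec in corrected:
        if str(meta["metabolite"]) == tracer_metabolite:
            tracer_e[(str(meta["sample_id"]), str(meta["tissue"]))] = molecular_enrichment(vec)

    non_tracer_keys = {
        (str(m["sample_id"]), str(m["tissue"]))
        for m, _ in corrected
        if str(m["metabolite"]) != tracer_metabolite
    }
    unpaired = sorted(non_tracer_keys - set(tracer_e))
    if unpaired:
        raise PairingError(
            f"samples lack a {tracer_metabolite} row in their compartment: {unpaired}"
        )

    records = []
    max_n = max(vec.n_carbons for _, vec in corrected)
    for meta, vec in corrected:
        e = molecular_enrichment(vec)
        flags: list[str] = []
        key = (str(meta["sample_id"]), str(meta["tissue"]))
        if str(meta["metabolite"]) == tracer_metabolite:
            norm = 1.0 if e > 0 else math.nan
            if e == 0:
                flags.append(REASON_ZERO_TRACER)
        else:
            try:
                norm = normalized_enrichment(e, tracer_e[key])
            except DataError:
                norm = math.nan
                flags.append(REASON_ZERO_TRACER)
        cyc = math.nan
        if vec.n_carbons == 3:
            try:
                cyc = cycling_ratio(vec)
            except DataError:
                flags.append(REASON_ZERO_M3)
        rec = {
            "sample_id": meta["sample_id"],
            "group": meta["group"],
            "tissue": meta["tissue"],
            "metabolite": meta["metabolite"],
            "n_carbons": vec.n_carbons,
            "molecular_enrichment": e,
            "normalized_ratio": norm,
            "cycling_ratio": cyc,
            "flags": ";".join(flags),
        }
        for k in range(max_n + 1):
            rec[f"m{k}"] = vec.values[k] if k <= vec.n_carbons else math.nan
        records.append(rec)
    return pd.DataFrame.from_records(records)
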