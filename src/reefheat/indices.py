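"""Field-based reef sensitivity metrics from colony-level bleaching surveys.

A survey scores 150-200 coral colonies into four response categories
(normal, pale, partially bleached, fully bleached). From those counts this
module computes the bleaching severity index (BSI, reported on a 0-100
scale), a species-level severity table pooled across surveys, the reef
sensitivity index SI_reef (abundance-weighted species severity), the reef
functional index RFI (abundance-weighted functional coefficients with
congener fallback), species richness, Hill N1 diversity (exponential of
Shannon entropy, "effective species"), and the first-axis site scores of a
correspondence-analysis ordination of community composition (DCA1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "SurveyObservation",
    "SpeciesSensitivityTable",
    "FunctionalCoefficientTable",
    "ReefIndexSet",
    "bleaching_severity",
    "species_bsi_table",
    "si_reef",
    "rfi",
    "hill_n1",
    "richness",
    "dca_axis1",
    "reef_index_set",
]

#: Ordered response categories and their severity weights.
CATEGORIES = ("normal", "pale", "partially_bleached", "fully_bleached")
_WEIGHTS = {"normal": 0.0, "pale": 1.0, "partially_bleached": 2.0, "fully_bleached": 3.0}


@dataclass
class SurveyObservation:
    """One reef-level sample: colony counts by species and response category."""

    site_id: str
    date: pd.Timestamp
    latitude: float
    longitude: float
    depth: float
    colonies: list[tuple[str, str, int]]  # (species, category, count)

    def __post_init__(self) -> None:
        self.date = pd.Timestamp(self.date)
        if self.depth <= 0:
            raise ValueError(f"depth must be positive, got {self.depth}")
        total = 0
        for species, category, count in self.colonies:
            if category not in CATEGORIES:
                raise ValueError(
                    f"unknown category {category!r}; expected one of {CATEGORIES}"
                )
            if count < 1:
                raise ValueError(f"colony count must be >= 1, got {count}")
            total += count
        if total < 1:
            raise ValueError("survey holds no colonies")
        if not 150 <= total <= 200:
            warnings.warn(
                f"site {self.site_id} {self.date.date()}: {total} colonies "
                f"(survey protocol targets 150-200)",
                stacklevel=2,
            )

    @property
    def n_colonies(self) -> int:
        return sum(c for _, _, c in self.colonies)

    def category_counts(self) -> tuple[int, int, int, int]:
        """(n, c2, c3, c4): total, pale, partially bleached, fully bleached."""
        c = {cat: 0 for cat in CATEGORIES}
        for _, category, count in self.colonies:
            c[category] += count
        return (
            self.n_colonies,
            c["pale"],
            c["partially_bleached"],
            c["fully_bleached"],
        )

    def species_abundances(self) -> pd.Series:
        """Total colonies per species, all categories pooled."""
        counts: dict[str, int] = {}
        for species, _, count in self.colonies:
            counts[species] = counts.get(species, 0) + count
        return pd.Series(counts, dtype=float).sort_index()


def bleaching_severity(n: int, c2: int, c3: int, c4: int, scale: float = 100.0) -> float:
    """Bleaching severity index from category counts.

    ``100 * ((c2 + 2*c3 + 3*c4) / 3) / n`` with c2 pale, c3 partially
    bleached, c4 fully bleached colonies out of ``n`` total. The weighted
    proportion lies in [0, 1]; the default reporting scale multiplies by 100
    so that, e.g., a reef with 28% of colonies fully bleached (and the rest
    normal) scores 28.0.
    """
    if n < 1:
        raise ValueError("total colony count must be >= 1")
    if min(c2, c3, c4) < 0:
        raise ValueError("category counts must be non-negative")
    if c2 + c3 + c4 > n:
        raise ValueError(
            f"category counts sum to {c2 + c3 + c4} but only {n} colonies surveyed"
        )
    return scale * ((c2 + 2.0 * c3 + 3.0 * c4) / 3.0) / n


@dataclass
class SpeciesSensitivityTable:
    """Per-species bleaching severity on the [0, 1] scale, pooled over surveys."""

    table: pd.DataFrame  # index: species; columns: bsi_sp, n_colonies
    min_colonies: int

    def __post_init__(self) -> None:
        bad = self.table[(self.table["bsi_sp"] < 0) | (self.table["bsi_sp"] > 1)]
        if len(bad):
            raise ValueError(f"bsi_sp outside [0, 1] for {list(bad.index)}")

    @property
    def species(self) -> list[str]:
        return list(self.table.index)

    def bsi_sp(self, species: str) -> float:
        return float(self.table.loc[species, "bsi_sp"])


def species_bsi_table(
    surveys: list[SurveyObservation], min_colonies: int = 50
) -> SpeciesSensitivityTable:
    """Pool colonies across surveys and score each species' severity.

    Counts are summed per species across all surveys before applying the
    severity formula (pooling, not averaging per-survey values). Species
    with fewer than ``min_colonies`` pooled colonies are excluded and logged;
    a value of 500 reproduces the display rule used for the most abundant
    species in the source protocol.
    """
    if not surveys:
        raise ValueError("no surveys supplied")
    rows: dict[str, np.ndarray] = {}
    for obs in surveys:
        for species, category, count in obs.colonies:
            acc = rows.setdefault(species, np.zeros(2))
            acc[0] += count
            acc[1] += _WEIGHTS[category] * count
    if not rows:
        raise ValueError("surveys hold no colonies")
    records = {}
    for species, (n, weighted) in sorted(rows.items()):
        if n < min_colonies:
            logger.info(
                "species %s excluded from sensitivity table (%d < %d colonies)",
                species, int(n), min_colonies,
            )
            continue
        records[species] = {"bsi_sp": (weighted / 3.0) / n, "n_colonies": int(n)}
    if not records:
        raise ValueError(
            f"no species reaches the {min_colonies}-colony floor for the "
            f"sensitivity table"
        )
    table = pd.DataFrame.from_dict(records, orient="index")
    return SpeciesSensitivityTable(table=table, min_colonies=min_colonies)


def si_reef(observation: SurveyObservation, table: SpeciesSensitivityTable) -> float:
    """Reef sensitivity index: abundance-weighted mean species severity.

    Relative abundances are expressed in percent of classifiable colonies
    (colonies of species absent from the sensitivity table are excluded from
    both numerator and denominator, and logged), divided by 100 and weighted
    by the species severity on the [0, 1] scale. The result is a convex
    combination of the contributing species' severities.
    """
    ab = observation.species_abundances()
    known = ab.index.intersection(table.table.index)
    dropped = ab.index.difference(known)
    if len(dropped):
        logger.info(
            "site %s: %d colonies of %d species without a sensitivity value "
            "excluded from SI_reef",
            observation.site_id, int(ab[dropped].sum()), len(dropped),
        )
    if len(known) == 0:
        raise ValueError(
            f"site {observation.site_id}: no surveyed species overlaps the "
            f"sensitivity table"
        )
    ncc = 100.0 * ab[known] / ab[known].sum()
    return float((ncc / 100.0 * table.table.loc[known, "bsi_sp"]).sum())


@dataclass
class FunctionalCoefficientTable:
    """Species functional coefficients with congener-fallback provenance."""

    table: pd.DataFrame  # index: species; columns: fc, source_species

    def __post_init__(self) -> None:
        if (self.table["fc"] <= 0).any():
            raise ValueError("functional coefficients must be positive")

    def lookup(self, species: str) -> tuple[float, str] | None:
        """(fc, source species) for a species, falling back to a congener.

        Congeners share the genus (the first whitespace-separated token of
        the species name); ties are broken alphabetically for determinism.
        Returns None when no value can be assigned.
        """
        if species in self.table.index:
            return float(self.table.loc[species, "fc"]), species
        genus = species.split()[0]
        congeners = sorted(
            s for s in self.table.index if s.split()[0] == genus and s != species
        )
        if congeners:
            src = congeners[0]
            logger.info("species %s: using congener %s functional coefficient", species, src)
            return float(self.table.loc[src, "fc"]), src
        return None


def rfi(observation: SurveyObservation, fc_table: FunctionalCoefficientTable) -> float:
    """Reef functional index: abundance-weighted functional coefficient.

    Species without a coefficient use a congener's value when one exists;
    colonies that still cannot be assigned are dropped from the calculation.
    """
    ab = observation.species_abundances()
    fc_vals, kept = [], []
    for species in ab.index:
        hit = fc_table.lookup(species)
        if hit is None:
            logger.info(
                "site %s: %d colonies of %s dropped from RFI (no functional "
                "coefficient or congener)",
                observation.site_id, int(ab[species]), species,
            )
            continue
        kept.append(species)
        fc_vals.append(hit[0])
    if not kept:
        raise ValueError(
            f"site {observation.site_id}: no species with an assignable "
            f"functional coefficient"
        )
    ab_kept = ab[kept]
    ncc = 100.0 * ab_kept / ab_kept.sum()
    return float((ncc / 100.0 * np.asarray(fc_vals)).sum())


def hill_n1(abundances) -> float:
    """Hill number N1: exponential of Shannon entropy, in effective species.

    Zero-count species are ignored; invariant under rescaling of counts.
    Equals the number of species exactly when abundances are uniform.
    """
    a = np.asarray(pd.Series(abundances), dtype=float)
    a = a[a > 0]
    if a.size == 0 or a.sum() <= 0:
        raise ValueError("total abundance must be positive")
    p = a / a.sum()
    return float(np.exp(-(p * np.log(p)).sum()))


def richness(abundances) -> int:
    """Number of species with positive abundance."""
    a = np.asarray(pd.Series(abundances), dtype=float)
    n = int((a > 0).sum())
    if n == 0:
        warnings.warn("community has no species with positive abundance", stacklevel=2)
    return n


# ---------------------------------------------------------------------------
# Correspondence-analysis ordination (DCA axis 1)
# ---------------------------------------------------------------------------


def dca_axis1(
    matrix: pd.DataFrame,
    detrend_segments: int = 26,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> pd.Series:
    """First-axis site scores of a correspondence-analysis ordination.

    ``matrix`` holds sites in rows and species in columns (any non-negative
    abundance scale). The first axis is extracted by reciprocal averaging
    iterated to convergence. Detrending by segments (the ``detrend_segments``
    knob, kept for interface parity) alters higher axes only, so the
    first-axis scores returned here coincide with plain correspondence
    analysis; no nonlinear axis rescaling is applied.

    The algebraic sign of the axis is arbitrary; it is fixed so the scores
    correlate positively with the relative abundance of the overall most
    abundant species (ties broken alphabetically), making pipelines
    reproducible.
    """
    if detrend_segments < 1:
        raise ValueError("detrend_segments must be >= 1")
    Y = matrix.astype(float).copy()
    if (Y.to_numpy() < 0).any():
        raise ValueError("abundances must be non-negative")
    empty_rows = Y.index[Y.sum(axis=1) == 0]
    empty_cols = Y.columns[Y.sum(axis=0) == 0]
    if len(empty_rows) or len(empty_cols):
        warnings.warn(
            f"dropping {len(empty_rows)} all-zero sites and "
            f"{len(empty_cols)} all-zero species before ordination",
            stacklevel=2,
        )
        Y = Y.drop(index=empty_rows, columns=empty_cols)
    if Y.shape[0] < 3 or Y.shape[1] < 3:
        raise ValueError(f"need >= 3 sites and >= 3 species, got {Y.shape}")

    A = Y.to_numpy()
    r = A.sum(axis=1)
    c = A.sum(axis=0)
    total = A.sum()
    # residual correspondence matrix: rank < 2 means no gradient to extract
    S = A / total - np.outer(r, c) / total**2
    if np.linalg.matrix_rank(S, tol=1e-12) < 1:
        raise ValueError("degenerate site-by-species matrix (rank < 2)")

    # reciprocal averaging for the dominant non-trivial axis
    x = np.arange(Y.shape[0], dtype=float)
    x -= np.average(x, weights=r)
    x /= np.sqrt(np.average(x**2, weights=r)) or 1.0
    for _ in range(max_iter):
        u = (A.T @ x) / c
        x_new = (A @ u) / r
        x_new -= np.average(x_new, weights=r)
        norm = np.sqrt(np.average(x_new**2, weights=r))
        if norm < 1e-14:
            raise ValueError("degenerate site-by-species matrix (rank < 2)")
        x_new /= norm
        if np.max(np.abs(x_new - x)) < tol or np.max(np.abs(x_new + x)) < tol:
            x = x_new
            break
        x = x_new
    # eigenvalue-scaled site scores (weighted unit variance times sqrt(lambda))
    u = (A.T @ x) / c
    lam = float(np.average(((A @ u) / r) * x, weights=r))
    scores = x * np.sqrt(max(lam, 0.0))

    # deterministic orientation: positive association with the dominant species
    totals = Y.sum(axis=0)
    dominant = sorted(totals.index[totals == totals.max()])[0]
    rel = (Y[dominant] / Y.sum(axis=1)).to_numpy()
    corr = float(np.corrcoef(scores, rel)[0, 1]) if np.std(rel) > 0 else 0.0
    if corr < 0 or (corr == 0 and scores[0] < 0):
        scores = -scores
    return pd.Series(scores, index=Y.index, name="dca1")


@dataclass
class ReefIndexSet:
    """All field-based metrics for one survey observation."""

    site_id: str
    date: pd.Timestamp
    depth: float
    bsi: float
    si_reef: float
    rfi: float | None
    richness: int
    diversity_n1: float
    dca1: float | None

    def __post_init__(self) -> None:
        if not 0.0 <= self.bsi <= 100.0:
            raise ValueError(f"bsi outside [0, 100]: {self.bsi}")
        if self.richness >= 1 and not (1.0 - 1e-9 <= self.diversity_n1 <= self.richness + 1e-9):
            raise ValueError(
                f"diversity {self.diversity_n1} outside [1, richness={self.richness}]"
            )

    def as_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "date": self.date,
            "depth": self.depth,
            "bsi": self.bsi,
            "si_reef": self.si_reef,
            "rfi": self.rfi,
            "richness": self.richness,
            "diversity_n1": self.diversity_n1,
            "dca1": self.dca1,
        }


def reef_index_set(
    observation: SurveyObservation,
    si_table: SpeciesSensitivityTable,
    fc_table: FunctionalCoefficientTable | None = None,
    dca_scores: pd.Series | None = None,
    dca_key=None,
) -> ReefIndexSet:
    """Bundle every field-based metric for one survey observation.

    ``dca_scores`` is the axis-1 score series from :func:`dca_axis1` computed
    over the full set of observations; ``dca_key`` selects this observation's
    row (defaults to the site id). RFI is omitted (None) when no functional
    coefficient table is supplied.
    """
    n, c2, c3, c4 = observation.category_counts()
    ab = observation.species_abundances()
    dca1 = None
    if dca_scores is not None:
        key = dca_key if dca_key is not None else observation.site_id
        dca1 = float(dca_scores[key])
    return ReefIndexSet(
        site_id=observation.site_id,
        date=observation.date,
        depth=observation.depth,
        bsi=bleaching_severity(n, c2, c3, c4),
        si_reef=si_reef(observation, si_table),
        rfi=rfi(observation, fc_table) if fc_table is not None else None,
        richness=richness(ab),
        diversity_n1=hill_n1(ab),
        dca1=dca1,
    )
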