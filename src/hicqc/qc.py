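"""Library quality metrics and the back-ligation estimator.

The dangling-ends statistic of a Hi-C library counts the excess of
inward/outward read pairs over same-orientation pairs::

    DE = (FR + RF) - (FF + RR)

Under random ligation the four orientations occur 1:1:1:1, so a positive
DE is classically read as undigested/unligated DNA.  In adapter-marked
libraries, however, part of that excess consists of *back-ligations* —
digested ends re-joined in their original order.  Because the adapter
marks true ligation junctions, the adapter content of each orientation
class separates the two:

    P1 = N * (y + c)                       (FF/RR pairs with adapter)
    P2 = P1 + DE * c + B * y               (FR/RF pairs with adapter)

where N is the number of FF/RR pairs, y the adapter-ligation frequency,
c the incidental (chance) adapter match rate, and B the number of
back-ligation events.  Inverting:

    y = P1 / N - c
    B = (P2 - P1 - DE * c) / y

and G = DE - B is the genuinely undigested/unligated remainder, giving the
corrected dangling-ends statistic DE - B.

P1, P2, N and the DE inside the estimator are computed on the short-insert
subset (mate-overlap-merged fragments < 300 bp), where a 150 bp paired-end
run sequences the whole fragment and the junction adapter cannot escape
detection.  The headline DE of a library report uses all cis valid pairs.

:class:`BackLigationModel` wraps the estimator in a model/results pair:
``fit()`` returns a :class:`BackLigationResults` carrying the point
estimates, bootstrap standard errors and a ``summary()`` table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1
INSERT_MAX_DEFAULT = 300
ORIENTATIONS = ("FR", "RF", "FF", "RR")
SAME = ("FF", "RR")
OPPOSITE = ("FR", "RF")


class EstimatorError(ValueError):
    """The back-ligation estimator is undefined for the given inputs."""


class EmptyInputError(EstimatorError):
    """No observations to estimate from."""


# ---------------------------------------------------------------------------
# orientation counts and DE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationCounts:
    """FR/RF/FF/RR tallies of cis valid pairs."""

    fr: int = 0
    rf: int = 0
    ff: int = 0
    rr: int = 0

    @property
    def n_same(self) -> int:
        """N: the adapter-eligible same-orientation (FF + RR) total."""
        return self.ff + self.rr

    @property
    def n_opposite(self) -> int:
        return self.fr + self.rf

    @property
    def total(self) -> int:
        return self.fr + self.rf + self.ff + self.rr

    def as_dict(self) -> dict[str, int]:
        return {"FR": self.fr, "RF": self.rf, "FF": self.ff, "RR": self.rr}


def count_orientations(
    pairs: pd.DataFrame,
    subset_rule: Callable[[pd.DataFrame], pd.Series] | pd.Series | None = None,
) -> OrientationCounts:
    """Tally orientations over valid, deduplicated cis pairs.

    ``subset_rule`` may be a boolean mask or a callable producing one
    (e.g. the short-insert selection); trans pairs are never counted.
    """
    mask = (pairs["status"] == "valid") & pairs["orientation"].isin(ORIENTATIONS)
    if subset_rule is not None:
        extra = subset_rule(pairs) if callable(subset_rule) else subset_rule
        mask &= extra
    counts = pairs.loc[mask, "orientation"].value_counts()
    return OrientationCounts(
        fr=int(counts.get("FR", 0)),
        rf=int(counts.get("RF", 0)),
        ff=int(counts.get("FF", 0)),
        rr=int(counts.get("RR", 0)),
    )


@dataclass(frozen=True)
class DanglingEnds:
    value: int
    anomalous: bool  # negative excess: more same-orientation than inward/outward


def dangling_ends(counts: OrientationCounts) -> DanglingEnds:
    """DE = (FR + RF) - (FF + RR); negative values flagged, not clipped."""
    de = counts.n_opposite - counts.n_same
    return DanglingEnds(value=de, anomalous=de < 0)


# ---------------------------------------------------------------------------
# closed-form estimator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackLigationEstimate:
    y: float          # adapter-ligation frequency
    b: float          # back-ligation events (raw closed form)
    g: float          # undigested/unligated remainder, G = DE - B
    b_clamped: float  # B clamped to [0, max(DE, 0)]
    clamped: bool


def estimate_back_ligation(p1: float, p2: float, n: float, de: float, c: float) -> BackLigationEstimate:
    """Invert the adapter-content equations for (y, B).

    Raises :class:`EmptyInputError` when ``n == 0`` and
    :class:`EstimatorError` when ``p1/n <= c`` (no evidence of adapter
    ligation, the estimator's domain boundary).
    """
    if n <= 0:
        raise EmptyInputError("no FF/RR pairs: N = 0")
    if not 0.0 <= c < 1.0:
        raise EstimatorError(f"c must be in [0, 1), got {c}")
    y = p1 / n - c
    if y <= 0:
        raise EstimatorError(
            f"P1/N = {p1 / n:.4g} <= c = {c:.4g}: no evidence of adapter ligation"
        )
    b = (p2 - p1 - de * c) / y
    b_clamped = min(max(b, 0.0), max(float(de), 0.0))
    return BackLigationEstimate(y=y, b=b, g=de - b, b_clamped=b_clamped,
                                clamped=b_clamped != b)


@dataclass(frozen=True)
class CorrectedDanglingEnds:
    corrected: float          # DE - B
    share: float              # B / DE, NaN when DE <= 0
    share_defined: bool


def corrected_dangling_ends(de: float, b: float) -> CorrectedDanglingEnds:
    """Corrected DEnds = DE - B and the back-ligation share B/DE."""
    if de > 0:
        return CorrectedDanglingEnds(de - b, b / de, True)
    return CorrectedDanglingEnds(de - b, float("nan"), False)


def estimate_incidental_rate(
    annotated_pairs: pd.DataFrame,
    insert_max: int = INSERT_MAX_DEFAULT,
) -> float:
    """Incidental adapter-match rate c from an adapter-free library.

    In a library prepared without the adapter y = 0, so the adapter-
    containing fraction of short-insert FF/RR pairs estimates c directly.
    Expects a pairs table annotated with ``insert`` and ``has_adapter``.
    """
    sub = _subset_mask(annotated_pairs, insert_max) & annotated_pairs["orientation"].isin(SAME)
    n = int(sub.sum())
    if n == 0:
        raise EmptyInputError("no short-insert FF/RR pairs to estimate c from")
    return float(annotated_pairs.loc[sub, "has_adapter"].sum() / n)


def _subset_mask(df: pd.DataFrame, insert_max: int) -> pd.Series:
    return (df["status"] == "valid") & (df["insert"] >= 0) & (df["insert"] < insert_max)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class BackLigationModel:
    """Back-ligation estimator over the short-insert subset of a library.

    Built either from the four category counts directly or from an
    annotated pairs table via :meth:`from_annotated_pairs`.  ``fit``
    computes the closed-form estimates and bootstrap standard errors.
    """

    def __init__(self, n_same: int, p1: int, n_opposite: int, p2: int, c: float = 0.0):
        if min(n_same, p1, n_opposite, p2) < 0:
            raise EstimatorError("counts must be non-negative")
        if p1 > n_same or p2 > n_opposite:
            raise EstimatorError("adapter-containing counts cannot exceed class totals")
        self.n_same = int(n_same)
        self.p1 = int(p1)
        self.n_opposite = int(n_opposite)
        self.p2 = int(p2)
        self.c = float(c)

    @classmethod
    def from_annotated_pairs(
        cls,
        annotated_pairs: pd.DataFrame,
        c: float = 0.0,
        insert_max: int = INSERT_MAX_DEFAULT,
    ) -> "BackLigationModel":
        """Build from a pairs table with ``orientation``, ``insert`` and
        ``has_adapter`` columns (see :func:`hicqc.pipeline.annotate_pairs`)."""
        sub = _subset_mask(annotated_pairs, insert_max)
        same = sub & annotated_pairs["orientation"].isin(SAME)
        opp = sub & annotated_pairs["orientation"].isin(OPPOSITE)
        return cls(
            n_same=int(same.sum()),
            p1=int(annotated_pairs.loc[same, "has_adapter"].sum()),
            n_opposite=int(opp.sum()),
            p2=int(annotated_pairs.loc[opp, "has_adapter"].sum()),
            c=c,
        )

    @property
    def de(self) -> int:
        """DE of the subset the estimator operates on."""
        return self.n_opposite - self.n_same

    def fit(self, n_boot: int = 200, seed: int | None = None) -> "BackLigationResults":
        est = estimate_back_ligation(self.p1, self.p2, self.n_same, self.de, self.c)
        boot = None
        if n_boot:
            boot = self._bootstrap(n_boot, seed)
        return BackLigationResults(self, est, boot)

    def _bootstrap(self, n_boot: int, seed: int | None) -> pd.DataFrame:
        """Resample pairs via the 4-category multinomial and re-estimate."""
        rng = np.random.default_rng(seed)
        total = self.n_same + self.n_opposite
        if total == 0:
            raise EmptyInputError("empty subset")
        probs = np.array(
            [self.p1, self.n_same - self.p1, self.p2, self.n_opposite - self.p2],
            dtype=float,
        ) / total
        draws = rng.multinomial(total, probs, size=n_boot)
        rows = []
        for sa, sn, oa, on in draws:
            n_same = sa + sn
            n_opp = oa + on
            try:
                e = estimate_back_ligation(sa, oa, n_same, n_opp - n_same, self.c)
                rows.append((e.y, e.b, e.g))
            except EstimatorError:
                rows.append((np.nan, np.nan, np.nan))
        return pd.DataFrame(rows, columns=["y", "b", "g"])


class BackLigationResults:
    """Fitted estimates with bootstrap uncertainties."""

    param_names = ("y", "b", "g")

    def __init__(self, model: BackLigationModel, estimate: BackLigationEstimate,
                 boot: pd.DataFrame | None):
        self.model = model
        self.estimate = estimate
        self._boot = boot

    # -- point estimates ----------------------------------------------------
    @property
    def params(self) -> pd.Series:
        e = self.estimate
        return pd.Series({"y": e.y, "b": e.b, "g": e.g})

    @property
    def b_clamped(self) -> float:
        return self.estimate.b_clamped

    @property
    def corrected_de(self) -> float:
        return corrected_dangling_ends(self.model.de, self.b_clamped).corrected

    @property
    def back_ligation_share(self) -> float:
        """Clamped share B/DE in [0, 1]; NaN when DE <= 0."""
        return corrected_dangling_ends(self.model.de, self.b_clamped).share

    @property
    def back_ligation_share_raw(self) -> float:
        return corrected_dangling_ends(self.model.de, self.estimate.b).share

    # -- uncertainties ------------------------------------------------------
    @property
    def bse(self) -> pd.Series:
        """Bootstrap standard errors of (y, b, g)."""
        if self._boot is None:
            return pd.Series({p: np.nan for p in self.param_names})
        return self._boot.std(ddof=1)

    @property
    def n_boot_failed(self) -> int:
        if self._boot is None:
            return 0
        return int(self._boot["b"].isna().sum())

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Percentile bootstrap confidence intervals."""
        if self._boot is None:
            raise EstimatorError("fitted without bootstrap replicates")
        lo = self._boot.quantile(alpha / 2)
        hi = self._boot.quantile(1 - alpha / 2)
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary(self) -> str:
        m = self.model
        lines = [
            "Back-ligation estimator (short-insert subset)",
            "=" * 46,
            f"N (FF+RR pairs)        {m.n_same:>12d}",
            f"P1 (with adapter)      {m.p1:>12d}",
            f"FR+RF pairs            {m.n_opposite:>12d}",
            f"P2 (with adapter)      {m.p2:>12d}",
            f"DE (subset)            {m.de:>12d}",
            f"c (incidental rate)    {m.c:>12.4f}",
            "-" * 46,
        ]
        bse = self.bse
        for name, label in (("y", "y  adapter-ligation freq"),
                            ("b", "B  back-ligation events"),
                            ("g", "G  undigested/unligated")):
            se = bse[name]
            se_s = f" +/- {se:.4g}" if np.isfinite(se) else ""
            lines.append(f"{label:<26s}{self.params[name]:>12.4g}{se_s}")
        lines.append("-" * 46)
        lines.append(f"corrected DE (subset)  {self.corrected_de:>12.4g}")
        share = self.back_ligation_share
        if np.isfinite(share):
            lines.append(f"back-ligation share    {share:>12.2%}")
        if self.estimate.clamped:
            lines.append("note: raw B outside [0, DE]; clamped value reported "
                         "(check the assumed incidental rate c)")
        if self.n_boot_failed:
            lines.append(f"note: {self.n_boot_failed} bootstrap replicates "
                         "fell outside the estimator's domain")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        e = self.estimate
        return f"<BackLigationResults y={e.y:.3g} B={e.b:.4g} G={e.g:.4g}>"


# ---------------------------------------------------------------------------
# library report
# ---------------------------------------------------------------------------

@dataclass
class LibraryQCReport:
    """Per-library quality metrics in the style of a Hi-C QC dashboard."""

    schema_version: int
    total_read_pairs: int
    n_reported: int                 # pairs reaching valid status pre-dedup
    reported_pairs_fraction: float  # mapping efficiency
    n_valid: int                    # valid after deduplication
    n_duplicates: int
    n_cis: int
    cis_fraction: float
    orientation_counts: dict[str, int]
    de: int                         # headline DE over all cis valid pairs
    de_anomalous: bool
    de_fraction: float              # DE / valid pairs ("FR-excess")
    subset: dict | None = None      # estimator inputs + estimates
    distance_hist: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def flat_row(self) -> dict:
        """One comparison-table row (used by multi-library reports)."""
        row = {
            "total_read_pairs": self.total_read_pairs,
            "reported_pairs_pct": 100.0 * self.reported_pairs_fraction,
            "valid_pairs": self.n_valid,
            "duplicates": self.n_duplicates,
            "cis_pct": 100.0 * self.cis_fraction,
            "de": self.de,
            "de_fraction": self.de_fraction,
        }
        if self.subset is not None:
            for key in ("n_same", "p1", "n_opposite", "p2", "de_subset", "c",
                        "y", "b", "b_se", "b_clamped", "corrected_de_subset",
                        "back_ligation_share"):
                row[key] = self.subset.get(key)
        return row

    @classmethod
    def from_dict(cls, d: dict) -> "LibraryQCReport":
        known = {f: d[f] for f in cls.__dataclass_fields__ if f in d}
        missing = set(cls.__dataclass_fields__) - set(known) - {"subset", "distance_hist"}
        if missing or d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"report schema mismatch (missing {sorted(missing)}, "
                f"version {d.get('schema_version')!r})"
            )
        return cls(**known)


def distance_histogram(separations: np.ndarray, n_bins: int = 40,
                       d_min: float = 10.0) -> dict:
    """Cis-separation histogram at log-spaced bins."""
    seps = np.asarray(separations, dtype=float)
    seps = seps[seps >= d_min]
    if seps.size == 0:
        return {"bin_edges": [], "counts": []}
    edges = np.logspace(math.log10(d_min), math.log10(max(seps.max(), d_min * 10)), n_bins + 1)
    counts, edges = np.histogram(seps, bins=edges)
    return {"bin_edges": edges.tolist(), "counts": counts.tolist()}


def summarize_library(
    pairs: pd.DataFrame,
    raw_read_count: int,
    results: BackLigationResults | None = None,
    insert_max: int = INSERT_MAX_DEFAULT,
) -> LibraryQCReport:
    """Assemble the per-library QC report.

    ``pairs`` is the (optionally annotated) extraction table;
    ``raw_read_count`` the total number of sequenced read pairs;
    ``results`` a fitted :class:`BackLigationResults` when the library has
    an adapter and FASTQ reads were available.
    """
    if raw_read_count <= 0:
        raise ValueError("raw_read_count must be positive")
    n_reported = int((pairs["status"].isin(["valid", "duplicate"])).sum())
    n_dup = int((pairs["status"] == "duplicate").sum())
    valid = pairs[pairs["status"] == "valid"]
    n_valid = len(valid)
    cis = valid[valid["orientation"].isin(ORIENTATIONS)]
    n_cis = len(cis)
    counts = count_orientations(pairs)
    de = dangling_ends(counts)
    subset_info = None
    if results is not None:
        m = results.model
        cde = corrected_dangling_ends(m.de, results.b_clamped)
        subset_info = {
            "insert_max": insert_max,
            "n_same": m.n_same,
            "p1": m.p1,
            "n_opposite": m.n_opposite,
            "p2": m.p2,
            "de_subset": m.de,
            "c": m.c,
            "y": float(results.params["y"]),
            "y_se": float(results.bse["y"]),
            "b": float(results.params["b"]),
            "b_se": float(results.bse["b"]),
            "b_clamped": results.b_clamped,
            "b_was_clamped": results.estimate.clamped,
            "g": float(results.params["g"]),
            "corrected_de_subset": cde.corrected,
            "back_ligation_share": cde.share if cde.share_defined else None,
            "back_ligation_share_raw": (
                results.back_ligation_share_raw
                if math.isfinite(results.back_ligation_share_raw) else None
            ),
        }
    return LibraryQCReport(
        schema_version=SCHEMA_VERSION,
        total_read_pairs=int(raw_read_count),
        n_reported=n_reported,
        reported_pairs_fraction=n_reported / raw_read_count,
        n_valid=n_valid,
        n_duplicates=n_dup,
        n_cis=n_cis,
        cis_fraction=(n_cis / n_valid) if n_valid else float("nan"),
        orientation_counts=counts.as_dict(),
        de=de.value,
        de_anomalous=de.anomalous,
        de_fraction=(de.value / n_valid) if n_valid else float("nan"),
        subset=subset_info,
        distance_hist=distance_histogram(cis["separation"].to_numpy()),
    )
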