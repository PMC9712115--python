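"""Plaque-assay quantification: serial-dilution titres, efficiency of
plaquing (EOP), editing penetrance and MOI arithmetic.

Titres come from 2 µl spots of 10x serial dilutions. The least-diluted
spot with a countable plaque number gives
``pfu/ml = count / (spot volume in ml x dilution factor)``. Clearing at
high concentration without discrete plaques is read as lysis from
without: productive infection is bounded above by 1 p.f.u. at the most
concentrated plaque-free dilution.

EOP normalizes mean p.f.u. of a condition to a non-targeting control:
``mean(pfu_condition) / mean(pfu_negativecontrol)``. Editing penetrance
is ``pfu_enrichment / pfu_negative`` per replicate, averaged across
independent editing attempts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

TNTC = "TNTC"  # too numerous to count
CLEARING = "CLEARING_NO_PLAQUES"  # lysis from without
NONE = "NONE"  # no plaques, no clearing

Count = Union[int, str]


class AssayError(ValueError):
    """Uninterpretable or inconsistent assay data."""


@dataclass
class SpotSeries:
    """One strain's spot row across a serial dilution."""

    strain_id: str
    dilution_factors: Sequence[float]  # e.g. (1, 0.1, 0.01, ...)
    counts: Sequence[Count]
    spot_volume_ul: float = 2.0

    def __post_init__(self) -> None:
        if self.spot_volume_ul <= 0:
            raise AssayError("spot volume must be positive")
        if len(self.dilution_factors) != len(self.counts):
            raise AssayError("need one count per dilution")
        dils = list(self.dilution_factors)
        if any(d <= 0 for d in dils) or any(
            b >= a for a, b in zip(dils, dils[1:])
        ):
            raise AssayError("dilution factors must be positive and strictly decreasing")
        for c in self.counts:
            if not (isinstance(c, int) or c in (TNTC, CLEARING, NONE)):
                raise AssayError(f"invalid count {c!r}")


@dataclass
class TitreEstimate:
    pfu_per_ml: float
    is_upper_bound: bool = False
    below_detection: bool = False
    source_dilution: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pfu_per_ml < 0:
            raise AssayError("titre cannot be negative")


def titre_from_spots(
    series: SpotSeries, count_range: tuple[int, int] = (1, 50)
) -> TitreEstimate:
    """Titre from the least-diluted countable spot, with the
    lysis-from-without upper-bound rule for plaque-free clearings."""
    lo, hi = count_range
    vol_ml = series.spot_volume_ul / 1000.0
    for dil, count in zip(series.dilution_factors, series.counts):
        if isinstance(count, int) and lo <= count <= hi:
            return TitreEstimate(
                pfu_per_ml=count / (vol_ml * dil), source_dilution=dil
            )
    # no countable spot: clearing -> upper bound of 1 p.f.u. at the most
    # concentrated dilution without individual plaques
    for dil, count in zip(series.dilution_factors, series.counts):
        if count == CLEARING:
            return TitreEstimate(
                pfu_per_ml=1.0 / (vol_ml * dil),
                is_upper_bound=True,
                source_dilution=dil,
            )
    if all(c == NONE or c == 0 for c in series.counts):
        return TitreEstimate(pfu_per_ml=0.0, below_detection=True)
    raise AssayError(
        f"strain {series.strain_id}: no countable spot "
        "(all spots too numerous to count; increase dilution)"
    )


@dataclass
class EOPResult:
    condition_mean_pfu: float
    control_mean_pfu: float
    eop: float
    fold_restriction: float
    replicates: int
    below_detection: bool = False


def eop(
    condition: Sequence[float], control: Sequence[float]
) -> EOPResult:
    """Efficiency of plaquing: mean condition titre over mean control titre."""
    if not condition or not control:
        raise AssayError("need at least one replicate per arm")
    mean_cond = sum(condition) / len(condition)
    mean_ctrl = sum(control) / len(control)
    if mean_ctrl <= 0:
        raise AssayError("control mean titre is zero; EOP undefined")
    value = mean_cond / mean_ctrl
    return EOPResult(
        condition_mean_pfu=mean_cond,
        control_mean_pfu=mean_ctrl,
        eop=value,
        fold_restriction=math.inf if value == 0 else 1.0 / value,
        replicates=len(condition),
        below_detection=mean_cond == 0,
    )


@dataclass
class PenetranceResult:
    per_replicate: list[float]
    penetrance: float
    sd: Optional[float]
    replicates: int
    warnings: list[str] = field(default_factory=list)


def penetrance(
    pfu_enrichment: Sequence[float], pfu_negative: Sequence[float]
) -> PenetranceResult:
    """Editing penetrance: per-replicate enrichment/negative titre ratio,
    averaged across independent editing attempts (mean +/- s.d.)."""
    if len(pfu_enrichment) != len(pfu_negative):
        raise AssayError("need paired enrichment/negative replicates")
    ratios, warnings = [], []
    for k, (e, n) in enumerate(zip(pfu_enrichment, pfu_negative), start=1):
        if n <= 0:
            warnings.append(f"replicate {k}: zero negative-control titre, excluded")
            continue
        ratios.append(e / n)
    if not ratios:
        raise AssayError("no replicate with a positive negative-control titre")
    mean = sum(ratios) / len(ratios)
    sd = (
        math.sqrt(sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1))
        if len(ratios) > 1
        else None
    )
    return PenetranceResult(
        per_replicate=ratios, penetrance=mean, sd=sd, replicates=len(ratios), warnings=warnings
    )


@dataclass
class InfectionSetup:
    cfu: float
    pfu: float

    def __post_init__(self) -> None:
        if self.cfu <= 0 or self.pfu < 0:
            raise AssayError("cfu must be positive and pfu non-negative")

    @property
    def moi(self) -> float:
        return self.pfu / self.cfu


def pfu_for_moi(cfu: float, moi: float) -> float:
    """Phage particles needed to infect ``cfu`` cells at the given MOI."""
    if cfu <= 0 or moi < 0:
        raise AssayError("cfu must be positive and moi non-negative")
    return cfu * moi


def moi_series(
    stock_titre: float, added_volume_ml: float, n_tenfold_dilutions: int, cfu: float
) -> list[float]:
    """MOIs achieved by adding a fixed volume of each member of a 10x serial
    dilution: MOI_i = stock x 10^-i x volume / cfu, i = 0..n."""
    if stock_titre < 0 or added_volume_ml < 0 or cfu <= 0 or n_tenfold_dilutions < 0:
        raise AssayError("inputs must be non-negative (cfu positive)")
    return [
        stock_titre * 10.0 ** (-i) * added_volume_ml / cfu
        for i in range(n_tenfold_dilutions + 1)
    ]


# ---------------------------------------------------------------------------
# Tabular I/O


def _parse_count(raw: str) -> Count:
    token = str(raw).strip().upper()
    if token in (TNTC, CLEARING, NONE):
        return token
    try:
        return int(float(token))
    except ValueError as exc:
        raise AssayError(f"unparseable count {raw!r}") from exc


def read_spot_table(path: str | Path) -> dict[tuple[str, str], SpotSeries]:
    """Read a spot-count table (TSV/CSV; columns strain, replicate, dilution,
    count, optional spot_volume_ul) into SpotSeries keyed by
    (strain, replicate)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"strain", "replicate", "dilution", "count"}
    if not required <= set(df.columns):
        raise AssayError(f"spot table needs columns {sorted(required)}")
    out: dict[tuple[str, str], SpotSeries] = {}
    for (strain, rep), grp in df.groupby(["strain", "replicate"], sort=False):
        grp = grp.assign(_dil=grp["dilution"].astype(float)).sort_values(
            "_dil", ascending=False
        )
        vol = float(grp["spot_volume_ul"].iloc[0]) if "spot_volume_ul" in grp else 2.0
        out[(str(strain), str(rep))] = SpotSeries(
            strain_id=str(strain),
            dilution_factors=tuple(grp["_dil"]),
            counts=tuple(_parse_count(c) for c in grp["count"]),
            spot_volume_ul=vol,
        )
    return out


def titre_table(
    series: dict[tuple[str, str], SpotSeries],
    count_range: tuple[int, int] = (1, 50),
) -> pd.DataFrame:
    rows = []
    for (strain, rep), s in series.items():
        t = titre_from_spots(s, count_range)
        rows.append(
            {
                "strain": strain,
                "replicate": rep,
                "pfu_per_ml": t.pfu_per_ml,
                "is_upper_bound": t.is_upper_bound,
                "below_detection": t.below_detection,
                "source_dilution": t.source_dilution,
            }
        )
    return pd.DataFrame(rows)
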