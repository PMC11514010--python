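"""Quantum yields, branching fractions and excited-state lifetime from a set
of competing first-order decay channels.

With three channels out of S1 — radiative (k_r), intersystem crossing to the
dark triplet (k_isc) and internal conversion to S0 (k_ic) — the fluorescence
quantum yield is the radiative branching fraction

    QYF = k_r / (k_r + k_isc + k_ic)

and the S1 lifetime is 1/(k_r + k_isc + k_ic).  The three branching fractions
sum to one by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

from .descriptors import S1_OPT, EmitterDescriptor, RateSet
from .rates import FCWDParams, compute_rates

__all__ = ["YieldReport", "quantum_yield", "percent_int", "yield_table"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class YieldReport:
    """Branching fractions (each in [0, 1], summing to 1) and S1 lifetime (s)."""

    qyf: float
    phi_isc: float
    phi_ic: float
    lifetime: float


def quantum_yield(r: RateSet) -> YieldReport:
    """Branching fractions and lifetime from a rate set.

    Missing channels count as zero; all channels zero is an error (the S1
    population would never decay and no yield is defined).
    """
    k_r = r.k_r or 0.0
    k_isc = r.k_isc or 0.0
    k_ic = r.k_ic or 0.0
    total = k_r + k_isc + k_ic
    if total <= 0:
        raise ValueError("all rates are zero: quantum yields and lifetime undefined")
    return YieldReport(
        qyf=k_r / total, phi_isc=k_isc / total, phi_ic=k_ic / total, lifetime=1.0 / total
    )


def percent_int(fraction: float) -> int:
    """Round a fraction to an integer percentage, half away from zero
    (7.57% -> 8, 33.5% -> 34)."""
    return int(Decimal(fraction * 100.0).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


_COLUMNS = [
    "name",
    "e_s1_ev",
    "f",
    "gap_s1_t1_ev",
    "socme_cm1",
    "k_r",
    "k_r_source",
    "k_isc",
    "k_isc_source",
    "k_ic",
    "k_ic_source",
    "qyf",
    "qyf_percent",
    "phi_isc",
    "phi_ic",
    "lifetime_s",
]


class EmitterComputationError(RuntimeError):
    """Raised when a row of a yield table fails; names the emitter."""

    def __init__(self, emitter: str, cause: Exception):
        super().__init__(f"emitter {emitter!r}: {cause}")
        self.emitter = emitter
        self.cause = cause


def yield_table(
    ds: Sequence[EmitterDescriptor],
    p: Optional[FCWDParams] = None,
    *,
    prefer_supplied: bool = True,
) -> pd.DataFrame:
    """One row per emitter with rates, provenance, yields and lifetime.

    Rows appear in input order.  Duplicate emitter names are kept (with a
    logged warning); a failing emitter aborts the table with an error naming
    it, so partial results are never mistaken for complete ones.
    """
    names = [d.name for d in ds]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        logger.warning("duplicate emitter names in yield table: %s", sorted(dupes))
    rows = []
    for d in ds:
        try:
            r = compute_rates(d, p, prefer_supplied=prefer_supplied)
            y = quantum_yield(r)
            ctx = d.context(S1_OPT)
            s1, t1 = ctx.state("S1"), ctx.state("T1")
            rows.append(
                {
                    "name": d.name,
                    "e_s1_ev": s1.energy,
                    "f": s1.oscillator_strength,
                    "gap_s1_t1_ev": s1.energy - t1.energy,
                    "socme_cm1": d.socme_s1_t1,
                    "k_r": r.k_r,
                    "k_r_source": r.provenance["k_r"],
                    "k_isc": r.k_isc,
                    "k_isc_source": r.provenance["k_isc"],
                    "k_ic": r.k_ic,
                    "k_ic_source": r.provenance["k_ic"],
                    "qyf": y.qyf,
                    "qyf_percent": percent_int(y.qyf),
                    "phi_isc": y.phi_isc,
                    "phi_ic": y.phi_ic,
                    "lifetime_s": y.lifetime,
                }
            )
        except Exception as exc:
            raise EmitterComputationError(d.name, exc) from exc
    return pd.DataFrame(rows, columns=_COLUMNS)
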