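"""Reference-gated multiplex mutation calling and mutation-rate estimation.

A chamber containing a mutant template lights up in both the reference
channel and the mutation channel (double positive); a wild-type-only
chamber is reference-positive but mutation-negative; an empty chamber is
dark in both.  A chamber positive in a mutation channel but *negative* in
the reference channel cannot contain a genuine template — such chambers
are counted as anomalous (suspect false positives from impurity
interference) and excluded from the mutant estimate.

The mutation rate is the ratio of the two Poisson concentration
estimates, in percent:

    P = C_mutant / C_reference x 100

where ``C_mutant`` is quantified from double-positive chambers and
``C_reference`` from all reference-positive chambers, each through
``C = -ln(1 - d/n) / Vd``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .chip_model import ChipLayout, PanelConfig
from .image_analysis import ChamberCallTable
from .quantification import QuantResult, poisson_concentration

__all__ = [
    "GateCounts",
    "MutationRateResult",
    "gate_chambers",
    "mutation_rate",
    "panel_report",
]


@dataclass(frozen=True)
class GateCounts:
    """Chamber classes for one mutation after reference gating."""

    double_positive: int   # ref+ and mutation+
    wild_only: int         # ref+ and mutation-
    empty: int             # ref- and mutation-
    anomalous: int         # ref- and mutation+ (suspect false positives)

    @property
    def total(self) -> int:
        return self.double_positive + self.wild_only + self.empty + self.anomalous


def gate_chambers(calls: ChamberCallTable, panel: PanelConfig) -> dict:
    """Partition filled chambers into gate classes per panel mutation.

    Returns ``{mutation label: GateCounts}``.  Anomalous chambers
    (mutation-positive but reference-negative) are reported, never used
    for quantification.
    """
    f = calls.frame
    ref_col = f"call_{panel.reference_channel}"
    if ref_col not in f.columns:
        raise ValueError(f"calls table lacks reference channel "
                         f"{panel.reference_channel!r}")
    filled = f["filled"].to_numpy(dtype=bool)
    ref = f[ref_col].to_numpy(dtype=bool) & filled
    out = {}
    for mut, ch in panel.target_map.items():
        col = f"call_{ch}"
        if col not in f.columns:
            raise ValueError(f"calls table lacks channel {ch!r} for "
                             f"mutation {mut!r}")
        m = f[col].to_numpy(dtype=bool) & filled
        out[mut] = GateCounts(
            double_positive=int((ref & m).sum()),
            wild_only=int((ref & ~m).sum()),
            empty=int((~ref & ~m & filled).sum()),
            anomalous=int((~ref & m).sum()),
        )
    return out


@dataclass(frozen=True)
class MutationRateResult:
    """Mutation-rate estimate for one mutation on one chip.

    ``P`` is ``c_mutant / c_reference x 100`` (percent); its confidence
    interval propagates the two Wilson intervals by interval arithmetic,
    which is conservative (wider than an exact ratio interval).  When the
    reference concentration is zero, ``P`` is NaN and
    ``zero_reference`` is set.
    """

    mutation: str
    c_reference: QuantResult
    c_mutant: QuantResult
    P: float
    ci_low: float
    ci_high: float
    double_positive_count: int
    anomalous_count: int = 0
    zero_reference: bool = False
    detected: bool = False

    def to_dict(self) -> dict:
        return {
            "mutation": self.mutation,
            "c_reference": self.c_reference.concentration,
            "c_mutant": self.c_mutant.concentration,
            "P_percent": self.P,
            "ci_low_percent": self.ci_low,
            "ci_high_percent": self.ci_high,
            "double_positive_count": self.double_positive_count,
            "anomalous_count": self.anomalous_count,
            "zero_reference": self.zero_reference,
            "detected": self.detected,
        }


def mutation_rate(calls: ChamberCallTable, panel: PanelConfig,
                  layout: ChipLayout, count_unfilled: bool = False,
                  gate: bool = True, min_double_positive: int = 1,
                  alpha: float = 0.05) -> dict:
    """Mutation-rate estimates for every mutation on a chip's panel.

    ``c_reference`` is quantified from reference-positive chambers and
    ``c_mutant`` from double-positive chambers (set ``gate=False`` to use
    all mutation-channel positives instead, for comparison).  A mutation
    counts as *detected* when at least ``min_double_positive``
    double-positive chambers are present.

    Returns ``{mutation label: MutationRateResult}``.
    """
    vd = layout.chamber_volume_ul
    n = calls.counted(count_unfilled=count_unfilled)
    gates = gate_chambers(calls, panel)
    d_ref = calls.positives(panel.reference_channel)
    c_ref = poisson_concentration(d_ref, n, vd, alpha=alpha)

    out = {}
    for mut, g in gates.items():
        d_mut = g.double_positive if gate else g.double_positive + g.anomalous
        c_mut = poisson_concentration(d_mut, n, vd, alpha=alpha)
        if c_ref.concentration <= 0:
            out[mut] = MutationRateResult(
                mutation=mut, c_reference=c_ref, c_mutant=c_mut,
                P=math.nan, ci_low=math.nan, ci_high=math.nan,
                double_positive_count=g.double_positive,
                anomalous_count=g.anomalous, zero_reference=True,
            )
            continue
        P = c_mut.concentration / c_ref.concentration * 100.0
        # conservative interval arithmetic on the ratio
        lo = (c_mut.ci_low / c_ref.ci_high * 100.0
              if c_ref.ci_high > 0 else 0.0)
        hi = (c_mut.ci_high / c_ref.ci_low * 100.0
              if c_ref.ci_low > 0 else math.inf)
        out[mut] = MutationRateResult(
            mutation=mut, c_reference=c_ref, c_mutant=c_mut, P=P,
            ci_low=lo, ci_high=hi,
            double_positive_count=g.double_positive,
            anomalous_count=g.anomalous,
            detected=g.double_positive >= min_double_positive,
        )
    return out


def panel_report(chips, mutations, reporting_threshold: float | None = None
                 ) -> pd.DataFrame:
    """Merge per-chip mutation-rate results into one multi-mutation report.

    Two 3-plex chips cover a six-mutation panel on two chips.  Each
    mutation must appear in exactly one chip's results; a duplicate
    assignment is a configuration error, a missing mutation yields a
    placeholder row flagged ``missing_panel``.

    Parameters
    ----------
    chips : list of (chip_id, {mutation: MutationRateResult})
    mutations : list of str
        The full panel the report must cover (typically 6 labels).
    reporting_threshold : float, optional
        If set, adds a ``flagged`` column marking mutations whose P (%)
        exceeds it, in addition to the per-chip detection rule.
    """
    seen = {}
    for chip_id, results in chips:
        for mut in results:
            if mut in seen:
                raise ValueError(
                    f"mutation {mut!r} assigned to both chip {seen[mut]!r} "
                    f"and chip {chip_id!r}"
                )
            seen[mut] = chip_id

    rows = []
    for mut in mutations:
        if mut not in seen:
            rows.append({"mutation": mut, "chip": None, "missing_panel": True,
                         "P_percent": math.nan, "detected": False})
            continue
        chip_id = seen[mut]
        res = dict(chips)[chip_id][mut]
        row = {"mutation": mut, "chip": chip_id, "missing_panel": False}
        row.update({k: v for k, v in res.to_dict().items() if k != "mutation"})
        rows.append(row)
    report = pd.DataFrame(rows)
    if reporting_threshold is not None:
        report["flagged"] = report["P_percent"] > reporting_threshold
    extra = set(seen) - set(mutations)
    if extra:
        raise ValueError(f"results contain mutations outside the requested "
                         f"panel: {sorted(extra)}")
    return report
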