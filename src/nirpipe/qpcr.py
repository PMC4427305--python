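"""Absolute qPCR quantification with inhibition correction.

Standard curves are least-squares fits of Cq against log10 input copies
over a plasmid dilution series (10^1..10^9 copies). Amplification
efficiency is ``10^(-1/slope) - 1``; the detection limit is the lowest
standard level at which every replicate amplified. Unknowns are read off
the curve, averaged on the copy scale across replicates, corrected for
PCR inhibition (factor = fractional recovery of a known DNA spike in the
sample matrix) and scaled to copies per gram of sediment. Ratios of a
functional gene to the 16S rRNA gene normalise guild abundance to total
bacterial abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class QpcrError(ValueError):
    pass


@dataclass
class StandardCurve:
    target: str
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    detection_limit: float

    def copies(self, cq: float) -> float:
        """Invert the curve: copies per reaction from a Cq value."""
        return float(10 ** ((cq - self.intercept) / self.slope))

    def cq(self, copies: float) -> float:
        return float(self.slope * np.log10(copies) + self.intercept)

    @property
    def efficiency_flagged(self) -> bool:
        """True when efficiency falls outside the accepted 60-110% window."""
        return not 0.6 <= self.efficiency <= 1.1


def fit_standard_curve(
    standards: pd.DataFrame | list[tuple[float, float]], target: str = ""
) -> StandardCurve:
    """Fit Cq = slope*log10(copies) + intercept over a dilution series.

    ``standards``: (copies, Cq) pairs; NaN Cq marks a non-amplified
    replicate. Requires >= 4 distinct detected dilution levels; a positive
    slope (more template, later Cq) indicates inverted data and errors out.
    """
    if isinstance(standards, pd.DataFrame):
        pairs = list(zip(standards["copies"], standards["cq"]))
    else:
        pairs = list(standards)
    detected = [(c, q) for c, q in pairs if np.isfinite(q)]
    levels = sorted({c for c, _ in detected})
    if len(levels) < 4:
        raise QpcrError(f"need >= 4 distinct dilution levels, got {len(levels)}")
    x = np.log10([c for c, _ in detected])
    y = np.array([q for _, q in detected])
    fit = sps.linregress(x, y)
    if fit.slope >= 0:
        raise QpcrError("positive slope: Cq should decrease with input copies")
    # detection limit: lowest level where every replicate amplified
    by_level: dict[float, list[float]] = {}
    for c, q in pairs:
        by_level.setdefault(c, []).append(q)
    complete = [c for c, qs in by_level.items() if all(np.isfinite(q) for q in qs)]
    limit = min(complete) if complete else np.nan
    efficiency = float(10 ** (-1.0 / fit.slope) - 1.0)
    return StandardCurve(
        target=target,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        efficiency=efficiency,
        detection_limit=float(limit),
    )


def inhibition_factor(
    spiked_cq: float,
    spike_copies: float,
    curve: StandardCurve,
    background_copies: float = 0.0,
) -> float:
    """Fractional spike recovery in the sample matrix, clamped to (0, 1].

    ``background_copies`` is the (uncorrected) estimate of the sample's own
    template measured without the spike, so that
    factor = (recovered - background) / spike. Requires either a spike well
    above background (>= 10x) or an explicit background estimate; a
    recovery above 1.2 signals inconsistent data.
    """
    recovered = curve.copies(spiked_cq)
    factor = (recovered - background_copies) / spike_copies
    if factor > 1.2:
        raise QpcrError(
            f"spike recovery {factor:.2f} exceeds 1.2: inconsistent spike data"
        )
    return float(min(1.0, max(factor, 1e-12)))


@dataclass
class QuantResult:
    sample: str
    target: str
    mean_uncorrected: float
    sd_uncorrected: float
    inhibition: float
    copies_per_g: float
    sd_copies_per_g: float
    censored: bool
    n_replicates: int

    def ratio_to(self, reference: "QuantResult") -> float:
        """Target:reference copy ratio, reported to 4 decimals."""
        if reference.censored or reference.copies_per_g <= 0:
            raise QpcrError("reference quantification censored or non-positive")
        return copy_ratio(self.copies_per_g, reference.copies_per_g)


def copy_ratio(target_copies: float, reference_copies: float) -> float:
    """Corrected copy-number ratio (e.g. nirK/16S), to 4 decimals."""
    if reference_copies <= 0:
        raise QpcrError("reference copies must be positive")
    return round(target_copies / reference_copies, 4)


def quantify_corrected(
    sample: str,
    target: str,
    cq_replicates: list[float],
    curve: StandardCurve,
    inhibition: float = 1.0,
    dilution_factor: float = 1.0,
    extract_volume_ul: float = 50.0,
    template_volume_ul: float = 2.5,
    sediment_mass_g: float = 1.0,
) -> QuantResult:
    """Per-replicate copies from the curve, averaged, corrected, per gram.

    copies/g = mean(copies_rxn) * dilution * (extract/template volume)
               / (inhibition factor * mass). Replicates are aggregated on
    the copy scale. Cq beyond the standard range by > 1 log10 raises an
    extrapolation warning; below-detection means are flagged censored.
    """
    if not 0 < inhibition <= 1.0:
        raise QpcrError("inhibition factor must lie in (0, 1]")
    if sediment_mass_g <= 0:
        raise QpcrError("sediment mass must be positive")
    cqs = np.asarray([q for q in cq_replicates if np.isfinite(q)], dtype=float)
    if cqs.size == 0:
        raise QpcrError(f"no detected replicates for {sample}/{target}")
    lo, hi = curve.cq(1e9), curve.cq(curve.detection_limit)
    if np.any(cqs > hi - curve.slope * 1.0) or np.any(cqs < lo + curve.slope * 1.0):
        warnings.warn(
            f"{sample}/{target}: Cq beyond the standard range by > 1 log10",
            stacklevel=2,
        )
    copies = np.array([curve.copies(q) for q in cqs])
    mean_u = float(copies.mean())
    sd_u = float(copies.std(ddof=1)) if copies.size > 1 else 0.0
    scale = dilution_factor * (extract_volume_ul / template_volume_ul) / (
        inhibition * sediment_mass_g
    )
    return QuantResult(
        sample=sample,
        target=target,
        mean_uncorrected=mean_u,
        sd_uncorrected=sd_u,
        inhibition=inhibition,
        copies_per_g=mean_u * scale,
        sd_copies_per_g=sd_u * scale,
        censored=bool(mean_u < curve.detection_limit),
        n_replicates=int(copies.size),
    )


# ---------------------------------------------------------------------------
# plate-level driver

def process_plate(
    plate: pd.DataFrame,
    dilution_factor: float = 1.0,
    extract_volume_ul: float = 50.0,
    template_volume_ul: float = 2.5,
    sediment_mass_g: float = 1.0,
    reference_target: str = "16S",
) -> tuple[dict[str, StandardCurve], pd.DataFrame]:
    """Full quantification of one plate table.

    Per target: fit the standard curve, estimate per-sample inhibition from
    spike wells (spike amount in the ``copies`` column, background from the
    sample's own unknown wells), quantify unknowns and attach ratios to the
    reference target. Returns the curves and a tidy result table.
    """
    curves: dict[str, StandardCurve] = {}
    results: dict[tuple[str, str], QuantResult] = {}
    for target, sub in plate.groupby("target"):
        stds = sub[sub["role"] == "standard"]
        curve = fit_standard_curve(stds[["copies", "cq"]], target=target)
        curves[target] = curve
        unknowns = sub[sub["role"] == "unknown"]
        spikes = sub[sub["role"] == "spike"]
        for sample, usub in unknowns.groupby("sample"):
            cqs = list(usub["cq"])
            raw = quantify_corrected(
                sample, target, cqs, curve, 1.0, dilution_factor,
                extract_volume_ul, template_volume_ul, sediment_mass_g,
            )
            ssub = spikes[spikes["sample"] == sample]
            if len(ssub):
                facs = [
                    inhibition_factor(q, c, curve, raw.mean_uncorrected)
                    for q, c in zip(ssub["cq"], ssub["copies"])
                ]
                factor = float(np.mean(facs))
            else:
                factor = 1.0
            results[(sample, target)] = quantify_corrected(
                sample, target, cqs, curve, factor, dilution_factor,
                extract_volume_ul, template_volume_ul, sediment_mass_g,
            )

    rows = []
    for (sample, target), r in sorted(results.items()):
        row = {
            "sample": sample,
            "target": target,
            "copies_per_g": r.copies_per_g,
            "sd": r.sd_copies_per_g,
            "inhibition_factor": r.inhibition,
            "censored": r.censored,
        }
        ref = results.get((sample, reference_target))
        if target != reference_target and ref is not None and not ref.censored:
            row["ratio_to_reference"] = copy_ratio(r.copies_per_g, ref.copies_per_g)
        rows.append(row)
    return curves, pd.DataFrame(rows)
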