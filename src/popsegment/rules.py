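"""Need/complexity classification of segments from mean utilisation ratios.

A segment is compared with the whole study population setting by setting
(the seven utilisation variables).  The rule of thumb:

* **high need** if (i) mean activity is more than 100% above the
  population mean in any care setting, or (ii) more than 20% above in
  four or more care settings;
* **high complexity** if mean activity is higher than the population
  mean in four or more care settings.

Thresholds are strict inequalities ("more than") and configurable via
:class:`~popsegment.cohort.RunConfig`.  The classifier always reports the
literal rule's output; when a reference characterisation is supplied it
additionally emits a discrepancy report rather than overriding the rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import RunConfig, UTIL_COLS


@dataclass
class UtilisationRatioProfile:
    """Per-setting segment-to-population mean utilisation ratios.

    Settings where the population mean is zero have an undefined ratio
    (NaN) and are excluded from all threshold counting.
    """

    segment: int
    segment_means: np.ndarray
    population_means: np.ndarray
    ratios: np.ndarray
    defined: np.ndarray      # boolean mask of settings with a defined ratio


@dataclass
class NeedComplexityLabel:
    segment: int
    need: str                # "high" | "low"
    complexity: str          # "high" | "low"
    fired_criteria: dict[str, list[str]]


def utilisation_ratios(segment_means, population_means,
                       segment: int = 0) -> UtilisationRatioProfile:
    """Elementwise segment-mean / population-mean ratios."""
    seg = np.asarray(segment_means, dtype=float)
    pop = np.asarray(population_means, dtype=float)
    if seg.shape != pop.shape or seg.shape != (len(UTIL_COLS),):
        raise ValueError("expected one mean per utilisation variable")
    if (seg < 0).any() or (pop < 0).any():
        raise ValueError("utilisation means must be non-negative")
    defined = pop > 0
    ratios = np.full_like(seg, np.nan)
    ratios[defined] = seg[defined] / pop[defined]
    return UtilisationRatioProfile(segment=segment, segment_means=seg,
                                   population_means=pop, ratios=ratios,
                                   defined=defined)


def classify_segment(profile: UtilisationRatioProfile,
                     config: RunConfig | None = None) -> NeedComplexityLabel:
    """Apply the need/complexity rule of thumb to a ratio profile."""
    config = config or RunConfig()
    r = profile.ratios
    ok = profile.defined
    settings = np.array(UTIL_COLS)

    any_hit = ok & (r > config.need_any_setting_ratio)
    multi_hit = ok & (r > config.need_multi_setting_ratio)
    complex_hit = ok & (r > config.complexity_ratio)

    need_i = bool(any_hit.any())
    need_ii = int(multi_hit.sum()) >= config.need_multi_setting_min
    high_complex = int(complex_hit.sum()) >= config.complexity_min_settings

    fired: dict[str, list[str]] = {}
    if need_i:
        fired["need_any_setting"] = list(settings[any_hit])
    if need_ii:
        fired["need_multi_setting"] = list(settings[multi_hit])
    if high_complex:
        fired["complexity"] = list(settings[complex_hit])

    return NeedComplexityLabel(
        segment=profile.segment,
        need="high" if (need_i or need_ii) else "low",
        complexity="high" if high_complex else "low",
        fired_criteria=fired,
    )


def classify_segments(segment_mean_table: pd.DataFrame, population_means,
                      config: RunConfig | None = None) -> list[NeedComplexityLabel]:
    """Classify every segment in a table of per-segment utilisation means.

    ``segment_mean_table`` is indexed by segment id with one column per
    utilisation variable (canonical names).
    """
    labels = []
    for seg, row in segment_mean_table.iterrows():
        prof = utilisation_ratios(row[list(UTIL_COLS)].to_numpy(dtype=float),
                                  population_means, segment=int(seg))
        labels.append(classify_segment(prof, config))
    return labels


def characterisation(label: NeedComplexityLabel) -> str:
    """Render a label in the conventional 'High Need, Low Complex' form."""
    return (f"{'High' if label.need == 'high' else 'Low'} Need, "
            f"{'High' if label.complexity == 'high' else 'Low'} Complex")


def discrepancy_report(labels: list[NeedComplexityLabel],
                       reference: pd.Series | dict) -> pd.DataFrame:
    """Compare literal-rule labels with a reference characterisation.

    Returns one row per segment with the rule's output, the reference
    label and an ``agrees`` flag.  The rule output is never altered to
    match the reference; disagreements are surfaced for human review.
    """
    ref = pd.Series(reference)
    rows = []
    for lab in labels:
        ours = characterisation(lab)
        theirs = str(ref.get(lab.segment, ""))
        rows.append({"segment": lab.segment, "rule": ours, "reference": theirs,
                     "agrees": ours.lower() == theirs.strip().lower()})
    return pd.DataFrame(rows).set_index("segment")
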