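"""ATC drug-class configuration.

Maps ATC codes onto the five antihypertensive monotherapy exposure classes,
fixed-dose combination (FDC) products, cohort-exclusion drug groups, and the
nine comorbidity drug groups used as risk factors.  All lists are prefix-based
(a code matches a group when it starts with any of the group's prefixes) and
editable: the exposure classes are fixed by the study design, while the
exclusion and comorbidity prefixes are documented defaults.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

EXPOSURE_CLASSES = ("thiazide", "ccb", "acei", "arb", "bb")

_DEFAULT_EXPOSURE = {
    "thiazide": ("C03AA",),
    "ccb": ("C08C", "C08D", "C08E"),
    "acei": ("C09A",),
    "arb": ("C09C",),
    "bb": ("C07A",),
}

# Antihypertensive fixed-dose combinations (count as switch/add-on targets).
_DEFAULT_FDC = (
    "C02L", "C03E", "C07B", "C07C", "C07D", "C07F", "C08G", "C09B", "C09D",
)

# Drugs whose presence around the index date signals acute cardiovascular
# disease or secondary hypertension: cardiac therapy (incl. acute CV and
# chronic heart failure drugs), migraine, systemic corticosteroids (adrenal),
# thyroid and parathyroid therapy.
_DEFAULT_EXCLUSION = ("C01", "N02C", "H02A", "H03", "H05")

# Subset of the exclusion list that also censors follow-up when it first
# appears after the index window (acute cardiovascular drug therapy).
_DEFAULT_ACUTE_CV = ("C01",)

_DEFAULT_COMORBIDITY = {
    "diabetes": ("A10",),
    "ra": ("M01C", "L04A"),
    "asthma_copd": ("R03",),
    "antiepileptics": ("N03",),
    "antiparkinson": ("N04",),
    "psycholeptics": ("N05",),
    "psychoanaleptics": ("N06",),
    "addictive_disorders": ("N07B",),
    "antineoplastics": ("L01",),
}

_ATC_RE = re.compile(r"^[A-Z][0-9A-Z]{0,6}$")


def is_valid_atc(code: str) -> bool:
    """True if *code* looks like a (possibly partial) ATC code."""
    return bool(_ATC_RE.match(str(code)))


@dataclass(frozen=True)
class ClassMap:
    """Prefix tables driving every ATC lookup in the pipeline."""

    exposure_classes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_EXPOSURE)
    )
    fdc_prefixes: tuple[str, ...] = _DEFAULT_FDC
    exclusion_prefixes: tuple[str, ...] = _DEFAULT_EXCLUSION
    acute_cv_prefixes: tuple[str, ...] = _DEFAULT_ACUTE_CV
    comorbidity_groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_COMORBIDITY)
    )

    def __post_init__(self) -> None:
        if set(self.exposure_classes) != set(EXPOSURE_CLASSES):
            raise ValueError(
                "exposure_classes must be exactly "
                f"{set(EXPOSURE_CLASSES)}, got {set(self.exposure_classes)}"
            )

    # -- lookups ---------------------------------------------------------

    def exposure_class_of(self, atc: str) -> str | None:
        """Exposure class name for *atc*, or None if not an exposure drug."""
        for name, prefixes in self.exposure_classes.items():
            if str(atc).startswith(prefixes):
                return name
        return None

    def is_fdc(self, atc: str) -> bool:
        return str(atc).startswith(self.fdc_prefixes)

    def is_exclusion(self, atc: str) -> bool:
        return str(atc).startswith(self.exclusion_prefixes)

    def is_acute_cv(self, atc: str) -> bool:
        return str(atc).startswith(self.acute_cv_prefixes)

    def comorbidity_group_of(self, atc: str) -> str | None:
        for name, prefixes in self.comorbidity_groups.items():
            if str(atc).startswith(prefixes):
                return name
        return None

    def with_overrides(self, **kwargs) -> "ClassMap":
        return replace(self, **kwargs)


DEFAULT_CLASS_MAP = ClassMap()

# Representative full ATC codes used by the synthetic generator, one per group.
REPRESENTATIVE_EXPOSURE_ATC = {
    "thiazide": "C03AA03",  # hydrochlorothiazide
    "ccb": "C08CA01",       # amlodipine
    "acei": "C09AA02",      # enalapril
    "arb": "C09CA01",       # losartan
    "bb": "C07AB02",        # metoprolol
}
REPRESENTATIVE_FDC_ATC = "C09BA02"
REPRESENTATIVE_COMORBIDITY_ATC = {
    "diabetes": "A10BA02",
    "ra": "M01CB01",
    "asthma_copd": "R03AC02",
    "antiepileptics": "N03AX09",
    "antiparkinson": "N04BA02",
    "psycholeptics": "N05BA01",
    "psychoanaleptics": "N06AB04",
    "addictive_disorders": "N07BA01",
    "antineoplastics": "L01XA01",
}
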