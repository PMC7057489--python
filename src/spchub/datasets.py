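"""Bundled example data: the Ontario provincial demonstration.

The model's published provincial demonstration scored twelve rural
Ontario communities that passed both selection filters (more than 5000
residents and more than a one-hour drive to the nearest palliative-care
centre).  The component scores and sub-scores below are that study's
printed values; they serve as a worked example and as regression
fixtures for the aggregation arithmetic.  The underlying census,
road-network and facility microdata are licensed and are not included —
only the community-level scores.

Three self-consistency caveats in the printed vulnerability table are
worth knowing about: for Haileybury, Hawkesbury and Parry Sound the
printed overall vulnerability score differs from the mean of the
printed sub-scores by 0.01-0.02 at two decimals (0.35 vs 0.34, 0.29 vs
0.28 and 0.32 vs 0.30 respectively), presumably because the published
sub-scores were themselves rounded before printing.  The other nine
rows reproduce exactly.
"""

from __future__ import annotations

from typing import Dict, List, NamedTuple, Tuple

from .model import ComponentScores, PcixSubscores

__all__ = [
    "ONTARIO_COMPONENTS",
    "ONTARIO_PCIX",
    "ONTARIO_READINESS",
    "PCIX_INCONSISTENT_ROWS",
    "ontario_components",
]


class OntarioRow(NamedTuple):
    population: float
    isolation: float
    vulnerability: float
    readiness: float
    printed_ssm: str


#: Final component scores and the printed overall score per community.
ONTARIO_COMPONENTS: Dict[str, OntarioRow] = {
    "Dryden": OntarioRow(0.81, 0.94, 0.29, 0.80, "0.71"),
    "Elliot Lake": OntarioRow(0.68, 0.45, 0.35, 0.60, "0.52"),
    "Fort Frances": OntarioRow(1.00, 0.93, 0.30, 0.80, "0.76"),
    "Goderich": OntarioRow(0.23, 0.22, 0.29, 0.60, "0.34"),
    "Haileybury": OntarioRow(0.56, 0.41, 0.34, 0.60, "0.48"),
    "Hawkesbury": OntarioRow(0.26, 0.16, 0.28, 0.60, "0.33"),
    "Kapuskasing": OntarioRow(0.46, 0.44, 0.33, 0.40, "0.41"),
    "Kenora": OntarioRow(0.87, 0.56, 0.29, 0.80, "0.63"),
    "Kincardine": OntarioRow(0.25, 0.27, 0.30, 0.80, "0.41"),
    "Kirkland Lake": OntarioRow(0.26, 0.26, 0.32, 0.80, "0.41"),
    "Parry Sound": OntarioRow(0.21, 0.25, 0.30, 1.00, "0.44"),
    "Perth": OntarioRow(0.19, 0.22, 0.27, 0.80, "0.37"),
}


#: Vulnerability (PCIX) sub-scores: (age, sex, alone, vandix) and the
#: printed overall vulnerability score.
ONTARIO_PCIX: Dict[str, Tuple[PcixSubscores, str]] = {
    "Dryden": (PcixSubscores(0.08, 0.46, 0.08, 0.53), "0.29"),
    "Elliot Lake": (PcixSubscores(0.13, 0.46, 0.12, 0.67), "0.35"),
    "Fort Frances": (PcixSubscores(0.10, 0.46, 0.10, 0.52), "0.30"),
    "Goderich": (PcixSubscores(0.11, 0.49, 0.09, 0.47), "0.29"),
    "Haileybury": (PcixSubscores(0.12, 0.51, 0.10, 0.67), "0.34"),
    "Hawkesbury": (PcixSubscores(0.09, 0.50, 0.08, 0.48), "0.28"),
    "Kapuskasing": (PcixSubscores(0.10, 0.47, 0.12, 0.64), "0.33"),
    "Kenora": (PcixSubscores(0.09, 0.42, 0.09, 0.55), "0.29"),
    "Kincardine": (PcixSubscores(0.12, 0.50, 0.10, 0.49), "0.30"),
    "Kirkland Lake": (PcixSubscores(0.10, 0.46, 0.10, 0.63), "0.32"),
    "Parry Sound": (PcixSubscores(0.18, 0.47, 0.10, 0.52), "0.30"),
    "Perth": (PcixSubscores(0.08, 0.43, 0.08, 0.49), "0.27"),
}

#: Rows whose printed overall PCIX differs from the mean of the printed
#: sub-scores (rounding upstream of publication); see module docstring.
PCIX_INCONSISTENT_ROWS = ("Haileybury", "Hawkesbury", "Parry Sound")


#: Readiness indicator contributions (community awareness, training and
#: education, telemedicine, adequate physician supply, momentum), each
#: 0.2 or 0, and the printed readiness score.
ONTARIO_READINESS: Dict[str, Tuple[Tuple[float, ...], str]] = {
    "Dryden": ((0.2, 0.2, 0.2, 0.2, 0.0), "0.8"),
    "Elliot Lake": ((0.2, 0.0, 0.2, 0.2, 0.0), "0.6"),
    "Fort Frances": ((0.2, 0.2, 0.2, 0.2, 0.0), "0.8"),
    "Goderich": ((0.2, 0.0, 0.2, 0.2, 0.0), "0.6"),
    "Haileybury": ((0.2, 0.2, 0.2, 0.0, 0.0), "0.6"),
    "Hawkesbury": ((0.0, 0.2, 0.2, 0.2, 0.0), "0.6"),
    "Kapuskasing": ((0.0, 0.0, 0.2, 0.2, 0.0), "0.4"),
    "Kenora": ((0.2, 0.2, 0.2, 0.2, 0.0), "0.8"),
    "Kincardine": ((0.2, 0.2, 0.2, 0.2, 0.0), "0.8"),
    "Kirkland Lake": ((0.2, 0.2, 0.2, 0.2, 0.0), "0.8"),
    "Parry Sound": ((0.2, 0.2, 0.2, 0.2, 0.2), "1.0"),
    "Perth": ((0.2, 0.2, 0.2, 0.2, 0.0), "0.8"),
}


def ontario_components() -> List[Tuple[str, ComponentScores, str]]:
    """(name, component scores, printed overall score) per community."""
    return [
        (name, ComponentScores(r.population, r.isolation, r.vulnerability,
                               r.readiness), r.printed_ssm)
        for name, r in ONTARIO_COMPONENTS.items()
    ]
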