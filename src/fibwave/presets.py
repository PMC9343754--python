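"""Multiplicative ion-current scaling presets.

Every electrophysiological condition in this package — atrial-fibrillation
ionic remodeling, PITX2 haploinsufficiency, fibrotic-cell remodeling, and
antiarrhythmic drug action — is expressed as a named map from ion-current
identifier to a non-negative multiplicative factor applied to the
corresponding maximal conductance (or maximal SR uptake flux for I_Caup) of
the Courtemanche–Ramirez–Nattel (CRN) cell model.  Conditions compose by
element-wise multiplication, e.g. the PITX2-deficient AF baseline is the AF
remodeling preset composed with the PITX2 modifier.

Drug presets are data, not code: they are read from a YAML table shipped
with the package (``data/drug_presets.yaml``).  The shipped factor values
are synthetic, literature-motivated placeholders (multi-channel block for
amiodarone, predominantly I_Kr/I_CaL/I_Na for dronedarone, predominantly
I_Na for flecainide); replace the YAML with measured per-dose block tables
for quantitative drug work.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

#: Canonical order of scalable currents.  This order defines the factor
#: vector layout used by the numerical kernels.
CURRENTS = (
    "I_Na", "I_to", "I_CaL", "I_Kur", "I_K1", "I_Kr", "I_Ks",
    "I_Caup", "I_NaK", "I_NaCa", "I_pCa", "I_bNa", "I_bCa",
)
_CURRENT_INDEX = {c: i for i, c in enumerate(CURRENTS)}


class PresetError(KeyError):
    """Unknown preset name or malformed preset request."""


@dataclass(frozen=True)
class ScalingPreset:
    """A named multiplicative ion-current modification.

    Parameters
    ----------
    name
        Identifier, e.g. ``"wt_af"`` or ``"amiodarone@10uM"``.
    factors
        Mapping current identifier -> factor.  Currents not listed default
        to 1.0 (unmodified).
    provenance
        Free-text citation / origin note.
    """

    name: str
    factors: dict[str, float] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for cur, fac in self.factors.items():
            if cur not in _CURRENT_INDEX:
                raise ValueError(f"unknown current identifier {cur!r}")
            if not np.isfinite(fac) or fac < 0:
                raise ValueError(f"factor for {cur} must be finite and >= 0, got {fac}")

    def factor(self, current: str) -> float:
        return float(self.factors.get(current, 1.0))

    def as_vector(self) -> np.ndarray:
        """Factor vector in :data:`CURRENTS` order (length 13)."""
        v = np.ones(len(CURRENTS))
        for cur, fac in self.factors.items():
            v[_CURRENT_INDEX[cur]] = fac
        return v

    def __eq__(self, other: object) -> bool:  # factor-map equality, name-insensitive
        if not isinstance(other, ScalingPreset):
            return NotImplemented
        return np.array_equal(self.as_vector(), other.as_vector())

    def __hash__(self) -> int:
        return hash(self.as_vector().tobytes())


IDENTITY = ScalingPreset("identity", {}, "neutral element")

#: Wild-type sinus rhythm: the unmodified CRN model (all currents at 100%).
WT_SR = ScalingPreset("wt_sr", {}, "CRN baseline, all currents 100%")

#: AF electrical remodeling: I_Na -10%, I_to -70%, I_CaL -70%, I_Kur -50%,
#: I_Caup -20%, I_K1 +110%.
WT_AF = ScalingPreset(
    "wt_af",
    {"I_Na": 0.90, "I_to": 0.30, "I_CaL": 0.30, "I_Kur": 0.50,
     "I_Caup": 0.80, "I_K1": 2.10},
    "chronic-AF ionic remodeling of the CRN model",
)

#: PITX2+/- haploinsufficiency relative to wild type: I_K1 -25%, I_Kr +100%.
PITX2_MODIFIER = ScalingPreset(
    "pitx2_modifier",
    {"I_K1": 0.75, "I_Kr": 2.0},
    "PITX2+/- deficient remodeling (Syeda-type)",
)

#: Fibrotic-cell ionic remodeling: I_K1 -50%, I_CaL -50%, I_Na -40%.
FIBROTIC_MODIFIER = ScalingPreset(
    "fibrotic_modifier",
    {"I_K1": 0.50, "I_CaL": 0.50, "I_Na": 0.60},
    "fibrotic myocyte ionic remodeling",
)


def compose(base: ScalingPreset, modifier: ScalingPreset,
            name: str | None = None) -> ScalingPreset:
    """Element-wise product of two presets (commutative, associative)."""
    factors = dict(base.factors)
    for cur, fac in modifier.factors.items():
        factors[cur] = factors.get(cur, 1.0) * fac
    # drop factors that multiplied back to exactly 1
    factors = {c: f for c, f in factors.items() if f != 1.0}
    if name is None:
        name = f"{base.name}*{modifier.name}"
    prov = "; ".join(p for p in (base.provenance, modifier.provenance) if p)
    return ScalingPreset(name, factors, prov)


# composed genotype baselines -------------------------------------------------

#: PITX2-deficient sinus rhythm (genotype modifier on the unmodified model).
PITX2_SR = compose(WT_SR, PITX2_MODIFIER, name="pitx2_sr")

#: PITX2-deficient AF baseline: AF remodeling x PITX2 modifier.
#: I_K1 composes to 2.10 x 0.75 = 1.575 (+58% rounded), I_Kr to 2.0.
PITX2_AF = compose(WT_AF, PITX2_MODIFIER, name="pitx2_af")


DRUGS = ("amiodarone", "dronedarone", "flecainide")
DOSE_LABELS = {"low": 0, "high": 1}


def _load_drug_table() -> dict:
    ref = importlib.resources.files("fibwave").joinpath("data/drug_presets.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


_drug_table_cache: dict | None = None


def drug_preset(drug: str, dose: str) -> ScalingPreset:
    """Resolve a (drug, dose-label) pair from the shipped YAML drug table.

    ``dose`` is ``"low"`` or ``"high"``; doses are independent per-dose
    factor tables, not points on a fitted dose-response curve.
    """
    global _drug_table_cache
    if _drug_table_cache is None:
        _drug_table_cache = _load_drug_table()
    table = _drug_table_cache
    if drug not in table:
        raise PresetError(f"unknown drug {drug!r}; available: {sorted(table)}")
    if dose not in table[drug]["doses"]:
        raise PresetError(f"unknown dose {dose!r} for {drug}; "
                          f"available: {sorted(table[drug]['doses'])}")
    entry = table[drug]["doses"][dose]
    return ScalingPreset(
        f"{drug}@{entry['dose_label']}",
        {c: float(f) for c, f in entry["factors"].items()},
        table[drug].get("provenance", ""),
    )


_STATIC_PRESETS = {
    "identity": IDENTITY,
    "wt_sr": WT_SR,
    "wt_af": WT_AF,
    "pitx2_modifier": PITX2_MODIFIER,
    "pitx2_sr_modifier": PITX2_MODIFIER,   # spec-friendly alias
    "pitx2_sr": PITX2_SR,
    "pitx2_af": PITX2_AF,
    "fibrotic_modifier": FIBROTIC_MODIFIER,
}


def make_preset(name: str, dose: str | None = None) -> ScalingPreset:
    """Look up a registered preset by name.

    Genotype/remodeling/fibrosis presets are built in; drug presets require
    a ``dose`` label (``"low"``/``"high"``) and resolve through the YAML
    drug table.
    """
    if name in _STATIC_PRESETS:
        return _STATIC_PRESETS[name]
    if name in DRUGS:
        if dose is None:
            raise TypeError(f"drug preset {name!r} requires a dose label ('low'/'high')")
        return drug_preset(name, dose)
    raise PresetError(f"unknown preset {name!r}; known: "
                      f"{sorted(_STATIC_PRESETS) + list(DRUGS)}")


def genotype_baseline(genotype: str, rhythm: str = "af") -> ScalingPreset:
    """Baseline preset for a genotype in a given rhythm context.

    genotype: ``"wild_type"`` | ``"pitx2_deficient"``;
    rhythm: ``"sr"`` | ``"af"``.
    """
    key = {("wild_type", "sr"): "wt_sr", ("wild_type", "af"): "wt_af",
           ("pitx2_deficient", "sr"): "pitx2_sr",
           ("pitx2_deficient", "af"): "pitx2_af"}.get((genotype, rhythm))
    if key is None:
        raise PresetError(f"unknown genotype/rhythm {(genotype, rhythm)!r}")
    return _STATIC_PRESETS[key]
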