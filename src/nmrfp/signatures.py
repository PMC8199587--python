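"""The packaged metabolite/macromolecule signature library.

Thirty-two serum signals are described by Lorentzian peak lists (standard
chemical-shift assignments), a weight class that governs pulse-sequence
attenuation, a quantification window for the univariate screen, a baseline
concentration, and a default early-vs-metastatic effect size (signed Cliff's
delta, positive = lower in metastatic serum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib.resources import files as _pkg_files

import yaml

WEIGHT_CLASSES = ("small_molecule", "macromolecule")


@dataclass(frozen=True)
class MetaboliteSignature:
    """One quantifiable signal: Lorentzian peaks + quantification window."""

    name: str
    peaks: tuple[tuple[float, float, float], ...]  # (center_ppm, rel_height, linewidth)
    weight_class: str
    quant_window: tuple[float, float]
    base_concentration: float = 1.0
    effect_size: float = 0.0

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"{self.name}: peak list empty")
        for center, height, width in self.peaks:
            if width <= 0:
                raise ValueError(f"{self.name}: linewidth must be positive")
            if not (0.2 <= center <= 10.0):
                raise ValueError(f"{self.name}: peak center {center} outside 0.2-10.0 ppm")
            if height <= 0:
                raise ValueError(f"{self.name}: relative height must be positive")
        lo, hi = self.quant_window
        if not lo < hi:
            raise ValueError(f"{self.name}: quant_window lo must be < hi")
        if self.weight_class not in WEIGHT_CLASSES:
            raise ValueError(f"{self.name}: unknown weight class {self.weight_class!r}")
        if abs(self.effect_size) > 1:
            raise ValueError(f"{self.name}: |effect size| cannot exceed 1")


def load_signatures() -> list[MetaboliteSignature]:
    """Load the packaged 32-signal library."""
    text = (_pkg_files("nmrfp") / "data" / "signatures.yaml").read_text()
    entries = yaml.safe_load(text)["signatures"]
    sigs = [
        MetaboliteSignature(
            name=e["name"],
            peaks=tuple(tuple(p) for p in e["peaks"]),
            weight_class=e["weight_class"],
            quant_window=tuple(e["quant_window"]),
            base_concentration=float(e["base_concentration"]),
            effect_size=float(e["effect_size"]),
        )
        for e in entries
    ]
    names = [s.name for s in sigs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate signature names in packaged library")
    return sigs


def default_effect_sizes() -> dict[str, float]:
    """Metabolite -> default signed Cliff's delta (early vs metastatic)."""
    return {s.name: s.effect_size for s in load_signatures()}
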