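"""Model-construction constants gathered in one place.

Defaults are the recommended values for the three-tier spring network:
a stiff spring k_b = 5e4 kJ/mol/nm^2 between consecutive beads, a soft
interface spring k_if = 50 kJ/mol/nm^2 between an atomistic C-alpha and
a coarse bead, a 1.4 nm creation cutoff for both distance-based tiers,
a 1 nm shell for the automatic MG region, and reaction-field
electrostatics with a dielectric of 80 at a cutoff of 2.5 sigma_max.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class CanvasConfig:
    k_b: float = 5.0e4  # kJ/mol/nm^2, consecutive-bead springs
    k_if: float = 50.0  # kJ/mol/nm^2, AT-to-coarse interface springs
    spring_cutoff: float = 1.4  # nm, creation threshold for k_nb / k_if tiers
    mg_shell: float = 1.0  # nm, automatic MG shell around the AT region
    knb_k0: float = 1.0e4  # kJ/mol/nm^2, k_nb(d) plateau value
    knb_dmin: float = 0.4  # nm, distance below which k_nb is clamped at k0
    knb_lambda: float = 0.5  # nm, k_nb decay length
    epsilon_rf: float = 80.0  # reaction-field dielectric
    cutoff_factor: float = 2.5  # recommended nonbonded cutoff = factor * sigma_max

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "CanvasConfig":
        """Flat ``key = value`` file; unknown keys are rejected."""
        values: dict[str, float] = {}
        fields = set(cls.__dataclass_fields__)
        with open(path) as fh:
            for n, raw in enumerate(fh, start=1):
                text = raw.split("#", 1)[0].split(";", 1)[0].strip()
                if not text:
                    continue
                if "=" not in text:
                    raise ValueError(f"{path}, line {n}: expected key = value")
                key, val = (t.strip() for t in text.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}, line {n}: unknown key {key!r}")
                values[key] = float(val)
        return cls(**values)
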