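"""Pipeline configuration.

All tunable thresholds live here so that one YAML block reproduces a run:

* ``tolerance`` (Å) — additive slack on covalent-radius sums for bond
  perception (0.45 Å).
* ``ratio_cutoff`` — a perceived haptic metal bond is cut when its metal
  distance exceeds ``ratio_cutoff`` times the shortest metal distance in
  the same haptic patch.
* ``e_cutoff_ev`` — magnitude of the orbital-energy cutoff E_C (eV).
  Extended Hückel orbital energies are negative for bound orbitals;
  orbitals with energy below ``-e_cutoff_ev`` are doubly occupied when
  counting ligand electrons.
* ``lumo_low_ev`` / ``homo_high_ev`` — frontier-orbital thresholds of the
  iterative charge adjustment (−9 eV and −10.2 eV).
* ``max_charge_adjustments`` — safety cap per adjustment direction.
* ``resonance_cap`` — maximum number of resonance candidates kept per
  ligand.
* ``prefer_carbene`` — prefer a neutral carbene over the equivalent
  ylide (charge-separated) representation when both solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .elements import ElementTables


@dataclass
class PipelineConfig:
    tolerance: float = 0.45
    ratio_cutoff: float = 1.3
    e_cutoff_ev: float = 10.0
    lumo_low_ev: float = -9.0
    homo_high_ev: float = -10.2
    max_charge_adjustments: int = 4
    resonance_cap: int = 500
    prefer_carbene: bool = True
    covalent_radius: dict = field(default_factory=dict)
    max_valence: dict = field(default_factory=dict)
    allowed_valences: dict = field(default_factory=dict)

    def tables(self) -> ElementTables:
        return ElementTables(
            covalent_radius=dict(self.covalent_radius),
            max_valence=dict(self.max_valence),
            allowed_valences={k: list(v) for k, v in self.allowed_valences.items()},
        )

    def snapshot(self) -> dict:
        """JSON/YAML-serializable snapshot sufficient to reproduce a run."""
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.snapshot(), fh, sort_keys=False)


DEFAULT_CONFIG = PipelineConfig()
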