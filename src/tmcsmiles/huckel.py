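"""Ligand charge assignment from extended Hückel occupancies.

For an isolated ligand the initial charge guess is

    q = Σ_i V_i − 2 · #{ψ_k : E(ψ_k) < E_C}

i.e. the total valence-electron count of the neutral atoms minus two
electrons per molecular orbital lying below the cutoff E_C.  Orbital
energies come from an extended Hückel calculation (YAeHMOP via RDKit's
``rdEHTTools``); bound orbitals are negative in this convention and the
cutoff sits at −10 eV.

Two iterative corrections follow, re-reading the fixed orbital ladder at
the new filling level each step (nothing is recomputed):

* a positive charge combined with a low-lying LUMO (E < −9 eV) is
  implausible — two electrons are added until it no longer holds;
* a charge of −2 or below combined with a high-lying HOMO (E > −10.2 eV)
  is implausible — two electrons are removed until either condition
  clears.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdEHTTools

from .config import PipelineConfig, DEFAULT_CONFIG
from .connectivity import LigandFragment
from .elements import ElementTables, DEFAULT_TABLES

logger = logging.getLogger(__name__)

HUCKEL_ENGINE = "rdkit.rdEHTTools (YAeHMOP)"


class HuckelError(RuntimeError):
    pass


@dataclass
class ChargeGuess:
    """Hückel orbital ladder, electron bookkeeping and resulting charge."""

    orbital_energies: np.ndarray  # eV, ascending
    n_valence_electrons: int
    q: int
    adjustments: list[tuple[int, str]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def n_occupied(self) -> int:
        """Number of doubly occupied orbitals at the current charge."""
        return (self.n_valence_electrons - self.q) // 2

    def homo_energy(self) -> float | None:
        n = self.n_occupied
        if n < 1 or n > len(self.orbital_energies):
            return None
        return float(self.orbital_energies[n - 1])

    def lumo_energy(self) -> float | None:
        n = self.n_occupied
        if n < 0 or n >= len(self.orbital_energies):
            return None
        return float(self.orbital_energies[n])


def _eht_orbital_energies(f: LigandFragment) -> np.ndarray:
    """Extended Hückel orbital energies (eV, ascending) for a fragment.

    The Hückel Hamiltonian depends only on elements and coordinates; the
    fragment bonds are attached merely to satisfy the mol interface.
    """
    rw = Chem.RWMol()
    for el in f.elements:
        a = Chem.Atom(el)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    conf = Chem.Conformer(f.n_atoms)
    for k, xyz in enumerate(f.coords):
        conf.SetAtomPosition(k, tuple(float(v) for v in xyz))
    rw.AddConformer(conf)
    for i, j in f.bonds:
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol, Chem.SANITIZE_FINDRADICALS | Chem.SANITIZE_SETCONJUGATION)
    ok, res = rdEHTTools.RunMol(mol)
    if not ok:
        raise HuckelError("extended Hückel calculation did not converge")
    return np.sort(np.asarray(res.GetOrbitalEnergies(), dtype=float))


def huckel_charge_guess(
    f: LigandFragment,
    tables: ElementTables = DEFAULT_TABLES,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> ChargeGuess:
    """Initial ligand charge from extended Hückel double occupancies."""
    if f.n_atoms == 0:
        raise ValueError("cannot compute a charge for an empty fragment")
    n_val = sum(tables.valence_electrons(el) for el in f.elements)
    try:
        energies = _eht_orbital_energies(f)
    except Exception as exc:  # never a silent crash: parity fallback
        q = -(n_val % 2)
        logger.warning(
            "Hückel engine failed (%s); parity-only charge %d assigned", exc, q
        )
        return ChargeGuess(
            orbital_energies=np.array([]),
            n_valence_electrons=n_val,
            q=q,
            flags=[f"huckel_failed: {exc}"],
        )
    n_occ = int((energies < -abs(config.e_cutoff_ev)).sum())
    q = n_val - 2 * n_occ
    guess = ChargeGuess(orbital_energies=energies, n_valence_electrons=n_val, q=q)
    if n_val % 2:
        guess.flags.append("odd_electron_count")
    logger.debug(
        "huckel guess q=%+d (V=%d, %d occupied, engine=%s)",
        q, n_val, n_occ, HUCKEL_ENGINE,
    )
    return guess


def adjust_charge(
    g: ChargeGuess, config: PipelineConfig = DEFAULT_CONFIG
) -> ChargeGuess:
    """Apply the iterative LUMO/HOMO plausibility rules to a charge guess.

    Idempotent: a second call finds both conditions already cleared.  An
    oscillation (both rules firing alternately) stops after the first
    direction and is flagged.
    """
    if g.orbital_energies.size == 0:
        return g
    steps = {"+2e": 0, "-2e": 0}
    while True:
        if max(steps.values()) >= config.max_charge_adjustments:
            g.flags.append("adjustment_cap")
            break
        lumo = g.lumo_energy()
        if g.q > 0 and lumo is not None and lumo < config.lumo_low_ev:
            if steps["-2e"]:
                g.flags.append("oscillation_guard")
                break
            g.q -= 2
            g.adjustments.append((-2, f"q>0 with LUMO {lumo:.2f} eV < {config.lumo_low_ev}"))
            steps["+2e"] += 1
            continue
        homo = g.homo_energy()
        if g.q <= -2 and homo is not None and homo > config.homo_high_ev:
            if steps["+2e"]:
                g.flags.append("oscillation_guard")
                break
            g.q += 2
            g.adjustments.append((+2, f"q<=-2 with HOMO {homo:.2f} eV > {config.homo_high_ev}"))
            steps["-2e"] += 1
            continue
        break
    return g
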