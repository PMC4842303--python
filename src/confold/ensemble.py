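"""Constrained/unconstrained ensemble composition and ligand binding.

If a structural feature X (a pair, a motif, ...) is expressible as a hard
constraint, its soft-constrained ensemble can be assembled from two plain
folds: the unconstrained partition function Z and the constrained Z[X].
Attaching a pseudo-energy E(X) to every structure satisfying X gives

    Z' = (Z - Z[X]) + Z[X] * exp(-E(X)/RT)

and the corresponding base-pair probabilities as weighted mixtures.  A
ligand binding a motif X with dissociation constant Kd at concentration c
is the special case E(X) = Delta G = RT ln(Kd/c), with the bound state
counted in addition to the unbound one:

    Z' = Z + Z[X] * exp(-Delta G/RT)

Composing K overlapping features this way needs 2^K constrained folds
(inclusion/exclusion); the equivalent per-recursion soft constraints in
the engine avoid that blow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constraints import GenericConstraintCallback
from .energy_model import Sequence, ThermoParams
from .grammar import DecompStep

_CLIP = 1e-12
_NEG_TOL = 1e-9


class EnsembleAlgebraError(ValueError):
    pass


def compose_partition(Z: float, Z_X: float, E_X: float,
                      thermo: ThermoParams | None = None) -> float:
    """Partition function of the ensemble with bonus E_X on feature X."""
    if not (0.0 <= Z_X <= Z * (1.0 + 1e-12)):
        raise EnsembleAlgebraError(f"need 0 <= Z[X] <= Z, got Z={Z}, Z[X]={Z_X}")
    rt = (thermo or ThermoParams()).RT
    return (Z - Z_X) + Z_X * math.exp(-E_X / rt)


def bpp_complement(p: np.ndarray, p_X: np.ndarray, Z: float, Z_X: float) -> np.ndarray:
    """Pair probabilities restricted to structures NOT satisfying X, as the
    weighted difference p - (Z[X]/Z) p[X] (normalized by the full Z)."""
    if p.shape != p_X.shape:
        raise EnsembleAlgebraError("probability matrices must have equal shapes")
    if not (0.0 <= Z_X <= Z * (1.0 + 1e-12)):
        raise EnsembleAlgebraError(f"need 0 <= Z[X] <= Z, got Z={Z}, Z[X]={Z_X}")
    out = p - (Z_X / Z) * p_X
    if (out < -_NEG_TOL).any():
        worst = float(out.min())
        raise EnsembleAlgebraError(
            f"inconsistent inputs: complement probability {worst} below -{_NEG_TOL}"
        )
    np.clip(out, 0.0, None, out=out)   # zero out -1e-9 < x < 0 roundoff
    return out


def bpp_compose(p: np.ndarray, p_X: np.ndarray, Z: float, Z_X: float,
                E_X: float, thermo: ThermoParams | None = None) -> np.ndarray:
    """Pair probabilities after attaching bonus E_X to feature X.

    p' = (Z/Z') * p[not X] + (Z[X] e^{-E_X/RT} / Z') * p[X], with Z' from
    :func:`compose_partition`; the first factor reduces to (Z-Z[X])/Z'
    for the complement probabilities normalized on their own ensemble."""
    rt = (thermo or ThermoParams()).RT
    z_prime = compose_partition(Z, Z_X, E_X, thermo)
    comp = bpp_complement(p, p_X, Z, Z_X)
    return (Z / z_prime) * comp + (Z_X * math.exp(-E_X / rt) / z_prime) * p_X


def binding_delta_G(Kd: float, c: float, thermo: ThermoParams | None = None) -> float:
    """Concentration-dependent binding free energy RT ln(Kd/c), kcal/mol."""
    if Kd <= 0 or c <= 0:
        raise EnsembleAlgebraError("Kd and concentration must be positive")
    return (thermo or ThermoParams()).RT * math.log(Kd / c)


def ligand_partition(Z: float, Z_X: float, Kd: float, c: float,
                     thermo: ThermoParams | None = None) -> float:
    """Z' = Z + Z[X] exp(-Delta G/RT): unbound states plus bound states."""
    if not (0.0 <= Z_X <= Z * (1.0 + 1e-12)):
        raise EnsembleAlgebraError(f"need 0 <= Z[X] <= Z, got Z={Z}, Z[X]={Z_X}")
    rt = (thermo or ThermoParams()).RT
    dg = binding_delta_G(Kd, c, thermo)
    return Z + Z_X * math.exp(-dg / rt)


# --------------------------------------------------------------------------
# interior-loop ligand motifs


@dataclass(frozen=True)
class LigandModel:
    """An interior-loop binding motif with its thermodynamics.

    ``motif`` holds the 5' and 3' strand strings including the delimiting
    pairs: the first/last characters of the 5' strand pair with the
    last/first characters of the 3' strand.  ``correction`` is an optional
    intra-motif helix correction (kcal/mol) added on top of Delta G.
    """

    motif: tuple[str, str]
    Kd: float
    concentration: float = 1.0
    correction: float = 0.0

    def __post_init__(self) -> None:
        if self.Kd <= 0 or self.concentration <= 0:
            raise EnsembleAlgebraError("Kd and concentration must be positive")
        if len(self.motif[0]) < 2 or len(self.motif[1]) < 2:
            raise EnsembleAlgebraError("motif strands must include the delimiting pairs")

    def delta_G(self, thermo: ThermoParams | None = None) -> float:
        return binding_delta_G(self.Kd, self.concentration, thermo)


#: the theophylline aptamer core abstracted to an interior loop
#: (5' strand GAUACCAG / 3' strand CCCUUGGCAGC, Kd = 0.32 uM)
THEOPHYLLINE = LigandModel(motif=("GAUACCAG", "CCCUUGGCAGC"), Kd=0.32e-6)


@dataclass(frozen=True)
class MotifPlacement:
    """One (i, j, k, l) interior loop matching a ligand motif."""

    i: int
    j: int
    k: int
    l: int
    energy: float


def scan_motif(seq: Sequence, ligand: LigandModel,
               thermo: ThermoParams | None = None) -> list[MotifPlacement]:
    """Pre-scan all interior-loop placements of the ligand motif.

    A placement (i, j, k, l) requires seq[i..k] to equal the 5' strand and
    seq[l..j] the 3' strand; (i, j) and (k, l) are the delimiting pairs of
    the interior loop.  Each placement carries Delta G + correction as the
    bonus to be applied at the matching interior-loop decomposition step.
    """
    s5, s3 = ligand.motif
    n = len(seq)
    res = str(seq)
    bonus = ligand.delta_G(thermo) + ligand.correction
    placements = []
    for i in range(1, n - len(s5) + 2):
        if res[i - 1:i - 1 + len(s5)] != s5:
            continue
        k = i + len(s5) - 1
        for l in range(k + 1, n - len(s3) + 2):
            if res[l - 1:l - 1 + len(s3)] != s3:
                continue
            j = l + len(s3) - 1
            if seq.pairable(i, j) and seq.pairable(k, l):
                placements.append(MotifPlacement(i, j, k, l, bonus))
    return placements


def _motif_cb(step: DecompStep, i: int, j: int, k: int, l: int, payload) -> float:
    if step is DecompStep.INTERIOR_LOOP:
        return payload.get((i, j, k, l), 0.0)
    return 0.0


def ligand_callback(placements: list[MotifPlacement]) -> GenericConstraintCallback:
    """Generic soft callback adding each placement's bonus whenever the DP
    evaluates exactly that interior loop."""
    table = {(p.i, p.j, p.k, p.l): p.energy for p in placements}
    return GenericConstraintCallback(_motif_cb, payload=table)


def load_ligand_config(path: str) -> LigandModel:
    """Flat key/value ligand config: motif5, motif3, Kd, concentration,
    correction."""
    entries: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace("=", " ").split()
            if len(parts) != 2:
                raise EnsembleAlgebraError(f"{path}:{lineno}: expected 'key value'")
            entries[parts[0]] = parts[1]
    try:
        return LigandModel(
            motif=(entries["motif5"].upper().replace("T", "U"),
                   entries["motif3"].upper().replace("T", "U")),
            Kd=float(entries["Kd"]),
            concentration=float(entries.get("concentration", "1.0")),
            correction=float(entries.get("correction", "0.0")),
        )
    except KeyError as exc:
        raise EnsembleAlgebraError(f"{path}: missing ligand key {exc}") from exc
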