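"""Strain invariants, von Mises stress and healing-window classification.

The mechanoregulation idea: the local mechanical stimulus in the fracture
gap steers tissue differentiation. Two rotation-invariant strain measures
summarize that stimulus per element:

* octahedral shear strain gamma_oct = (2/3) * sqrt((e1-e2)^2 + (e2-e3)^2 +
  (e3-e1)^2) over principal strains — distortional deformation;
* volumetric strain eps_vol = trace(eps) — volume change, a proxy for the
  hydrostatic pressure state.

Callus elements are classified into zones of the (gamma_oct, eps_vol)
plane: understimulated (too little stimulus, resorption risk),
intramembranous (direct bony healing), endochondral (healing via a
cartilage intermediate) and excessive (too much movement, healing
prevented). The healing window is the union of the intramembranous and
endochondral zones. Upper bounds are inclusive: a state exactly on a
boundary belongs to the lower-strain zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

ZONES = ("understimulated", "intramembranous", "endochondral", "excessive")


@dataclass
class HealingZoneConfig:
    """Zone thresholds on (gamma_oct, eps_vol); dimensionless strains.

    Defaults follow the +/-5% / +/-15% structure of the tissue-
    differentiation literature and are configurable; every report embeds
    the thresholds it used.
    """

    gamma_low: float = 0.0025
    eps_low: float = 0.0025
    gamma_im: float = 0.05
    eps_im: float = 0.05
    gamma_ec: float = 0.15
    eps_ec_compressive: float = -0.15
    eps_ec_tensile: float = 0.05

    def validate(self) -> None:
        if not (0 < self.gamma_low < self.gamma_im < self.gamma_ec):
            raise ValueError("require 0 < gamma_low < gamma_im < gamma_ec")
        vals = [self.eps_low, self.eps_im, self.eps_ec_compressive, self.eps_ec_tensile]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("zone bounds must be finite")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class HealingWindowResult:
    """Per-callus-element zone labels plus zone fractions.

    Fractions are reported both volume-weighted and by element count; on a
    uniform voxel mesh the two coincide.
    """

    zone_labels: np.ndarray  # (nc,) strings from ZONES
    element_ids: np.ndarray  # (nc,) element indices into the mesh
    volume_fractions: dict[str, float]
    count_fractions: dict[str, float]
    config: HealingZoneConfig

    @property
    def healing_window_volume_fraction(self) -> float:
        return (
            self.volume_fractions["intramembranous"]
            + self.volume_fractions["endochondral"]
        )

    @property
    def healing_window_count_fraction(self) -> float:
        return (
            self.count_fractions["intramembranous"]
            + self.count_fractions["endochondral"]
        )


def _check_symmetric(t: np.ndarray, tol: float, what: str) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    single = t.ndim == 2
    if single:
        t = t[None]
    if t.shape[-2:] != (3, 3):
        raise ValueError(f"{what} must be (..., 3, 3)")
    asym = np.abs(t - np.transpose(t, (0, 2, 1))).max(axis=(1, 2))
    scale = np.maximum(np.abs(t).max(axis=(1, 2)), 1e-300)
    if np.any(asym > tol * np.maximum(scale, 1.0)):
        raise ValueError(f"{what} tensor is not symmetric within tolerance")
    return t, single


def strain_invariants(eps: np.ndarray, tol: float = 1e-8):
    """Octahedral shear and volumetric strain of symmetric strain tensor(s).

    Returns ``(gamma_oct, eps_vol)``; both are frame-invariant, and
    gamma_oct >= 0 by construction.
    """
    t, single = _check_symmetric(eps, tol, "strain")
    sym = 0.5 * (t + np.transpose(t, (0, 2, 1)))
    e = np.linalg.eigvalsh(sym)  # principal strains, ascending
    eps_vol = e.sum(axis=1)
    d01 = e[:, 0] - e[:, 1]
    d12 = e[:, 1] - e[:, 2]
    d20 = e[:, 2] - e[:, 0]
    gamma = (2.0 / 3.0) * np.sqrt(d01**2 + d12**2 + d20**2)
    if single:
        return float(gamma[0]), float(eps_vol[0])
    return gamma, eps_vol


def von_mises(sigma: np.ndarray, tol: float = 1e-8):
    """Von Mises equivalent stress of symmetric stress tensor(s) in MPa."""
    t, single = _check_symmetric(sigma, tol, "stress")
    sym = 0.5 * (t + np.transpose(t, (0, 2, 1)))
    tr = np.trace(sym, axis1=1, axis2=2)
    dev = sym.copy()
    dev[:, np.arange(3), np.arange(3)] -= (tr / 3.0)[:, None]
    vm = np.sqrt(1.5 * np.einsum("eij,eij->e", dev, dev))
    if single:
        return float(vm[0])
    return vm


def classify_zone(gamma: np.ndarray, eps_vol: np.ndarray,
                  config: HealingZoneConfig | None = None) -> np.ndarray:
    """Assign each (gamma_oct, eps_vol) pair to its unique healing zone.

    The rules partition the plane: understimulated uses strict upper
    bounds; the intramembranous and endochondral zones use inclusive upper
    bounds, so boundary states fall into the lower-strain zone.
    """
    config = config or HealingZoneConfig()
    config.validate()
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    eps_vol = np.atleast_1d(np.asarray(eps_vol, dtype=float))
    if np.any(gamma < -1e-15):
        raise ValueError("gamma_oct must be nonnegative")
    out = np.full(gamma.shape, "excessive", dtype=object)
    under = (gamma < config.gamma_low) & (np.abs(eps_vol) < config.eps_low)
    im = (gamma <= config.gamma_im) & (np.abs(eps_vol) <= config.eps_im)
    ec = (
        (gamma <= config.gamma_ec)
        & (eps_vol >= config.eps_ec_compressive)
        & (eps_vol <= config.eps_ec_tensile)
    )
    out[ec] = "endochondral"
    out[im & ~under] = "intramembranous"
    out[under] = "understimulated"
    return out


def classify_healing(
    gamma: np.ndarray,
    eps_vol: np.ndarray,
    volumes: np.ndarray,
    element_ids: np.ndarray | None = None,
    config: HealingZoneConfig | None = None,
) -> HealingWindowResult:
    """Classify callus elements and compute per-zone fractions."""
    config = config or HealingZoneConfig()
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    eps_vol = np.atleast_1d(np.asarray(eps_vol, dtype=float))
    volumes = np.atleast_1d(np.asarray(volumes, dtype=float))
    if gamma.size == 0:
        raise ValueError("no fracture region defined")
    if not (gamma.shape == eps_vol.shape == volumes.shape):
        raise ValueError("gamma, eps_vol and volumes must have matching shapes")
    labels = classify_zone(gamma, eps_vol, config)
    vtot = volumes.sum()
    vol_frac = {z: float(volumes[labels == z].sum() / vtot) for z in ZONES}
    cnt_frac = {z: float(np.count_nonzero(labels == z) / labels.size) for z in ZONES}
    if element_ids is None:
        element_ids = np.arange(labels.size)
    return HealingWindowResult(
        zone_labels=labels,
        element_ids=np.asarray(element_ids),
        volume_fractions=vol_frac,
        count_fractions=cnt_frac,
        config=config,
    )


def evaluate_healing_window(solution, region: str = "callus",
                            config: HealingZoneConfig | None = None
                            ) -> HealingWindowResult:
    """Healing-window classification of a solved model's fracture region."""
    mesh = solution.mesh
    ids = mesh.elements_in_region(region)
    if ids.size == 0:
        raise ValueError("no fracture region defined")
    gamma, eps_vol = strain_invariants(solution.strain[ids])
    volumes = mesh.element_volumes()[ids]
    return classify_healing(gamma, eps_vol, volumes, element_ids=ids, config=config)


def peak_stress(solution, region: str) -> tuple[float, int]:
    """Maximum per-element von Mises stress over a region.

    Returns ``(sigma_vm_max_MPa, element_id)``; ties break toward the
    lowest element id (argmax over elements ordered by id).
    """
    ids = solution.mesh.elements_in_region(region)
    if ids.size == 0:
        raise ValueError(f"region {region!r} is empty or unknown")
    vm = von_mises(solution.stress[ids])
    k = int(np.argmax(vm))
    return float(vm[k]), int(ids[k])
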