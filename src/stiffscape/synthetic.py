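"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study's three data modalities:

* probe-level log2 expression matrices with gene-wise multi-probe
  structure, planted directional effects and a knockdown arm in which a
  chosen fraction of effects is abolished (or attenuated);
* pyramidal Hertz contact force-indentation ramps with a linear
  pre-contact baseline, Gaussian force noise and a setpoint cutoff;
* microscopy fields of elliptical cells with nuclei, controlled
  intensities and boundary roughness, together with exact label masks.

All generators are pure functions of (config, seed): identical seeds
give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .afm import FitParams, ForceCurve, pyramid_prefactor
from .imaging import LabeledImage
from .transcriptome import ProbeMatrix

__all__ = [
    "ArraySimConfig",
    "PlantedTruth",
    "CurveSimConfig",
    "ImageSimConfig",
    "gen_probe_matrix",
    "gen_force_curve",
    "gen_image",
]


@dataclass
class ArraySimConfig:
    """Study design for a synthetic probe-level array experiment.

    Defaults mirror the emulated experiment: 6 biological replicates per
    control arm (stiff/soft) and 2 per knockdown arm, probe intensities
    on the log2 (RMA) scale, an unexpressed probe component below the
    floor of 5, and planted per-probe effects of 1.0 log2 units.
    ``frac_gata2_dependent`` (default 0.3, between the observed affected
    fractions of the up and down lists) is the share of planted genes
    whose effect is abolished — or attenuated by
    ``dependence_attenuation`` < 1 — in the knockdown soft arm.
    """

    n_genes: int = 500
    probes_per_gene: tuple = (4, 10)  # inclusive uniform range
    frac_up: float = 0.10
    frac_down: float = 0.10
    frac_gata2_dependent: float = 0.30
    effect_log2fc: float = 1.0
    effect_sd: float = 0.15
    noise_sd: float = 0.10
    baseline_mean: float = 8.0
    baseline_sd: float = 1.2
    frac_unexpressed: float = 0.15
    unexpressed_mean: float = 3.0
    unexpressed_sd: float = 0.8
    n_reps_ctrl: int = 6
    n_reps_kd: int = 2
    dependence_attenuation: float = 1.0  # 1 = complete abolition
    min_expressed_probes_for_effect: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_up", "frac_down", "frac_gata2_dependent",
                     "frac_unexpressed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_up + self.frac_down > 1.0:
            raise ValueError("frac_up + frac_down must be <= 1")
        if self.n_reps_ctrl < 1 or self.n_reps_kd < 0:
            raise ValueError("replicate counts invalid")
        lo, hi = self.probes_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("probes_per_gene must satisfy 1 <= min <= max")


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic array: per-gene direction and
    knockdown dependence, per-probe expression flag and planted effect."""

    genes: pd.DataFrame  # gene_id, direction in {up,down,none}, gata2_dependent
    probes: pd.DataFrame  # probe_set_id, gene_id, expressed, effect_log2fc

    @property
    def up_genes(self) -> set:
        return set(self.genes.loc[self.genes.direction == "up", "gene_id"])

    @property
    def down_genes(self) -> set:
        return set(self.genes.loc[self.genes.direction == "down", "gene_id"])

    @property
    def dependent_genes(self) -> set:
        return set(self.genes.loc[self.genes.gata2_dependent, "gene_id"])

    def to_dict(self) -> dict:
        return {"genes": self.genes.to_dict(orient="records"),
                "probes": self.probes.to_dict(orient="records")}


_DESIGNS = {
    "stiffness_4arm": ("ctrl-stiff", "ctrl-soft", "kd-stiff", "kd-soft"),
    "oss_2arm": ("static", "OSS"),
}


def gen_probe_matrix(config: ArraySimConfig,
                     design: str = "stiffness_4arm") -> tuple[ProbeMatrix, PlantedTruth]:
    """Simulate a probe-level log2 expression matrix with planted effects.

    In the 4-arm stiffness design the planted shift appears in the soft
    arms; knockdown-dependent genes lose it (fully or per the attenuation
    factor) in the knockdown soft arm. In the 2-arm shear design the
    shift appears in the OSS arm and both arms carry ``n_reps_ctrl``
    replicates. Genes are only planted as regulated when they carry at
    least ``min_expressed_probes_for_effect`` expressed probes, the
    detection unit of the downstream min-probe rule.
    """
    if design not in _DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {sorted(_DESIGNS)}")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.probes_per_gene
    n_probes_per_gene = rng.integers(lo, hi + 1, size=config.n_genes)
    gene_ids = np.array([f"g{i + 1:05d}" for i in range(config.n_genes)])

    probe_gene = np.repeat(gene_ids, n_probes_per_gene)
    n_probes = probe_gene.size
    probe_ids = np.array([f"p{i + 1:07d}" for i in range(n_probes)])
    expressed = rng.random(n_probes) >= config.frac_unexpressed
    baseline = np.where(
        expressed,
        rng.normal(config.baseline_mean, config.baseline_sd, n_probes),
        rng.normal(config.unexpressed_mean, config.unexpressed_sd, n_probes),
    )

    # genes eligible to carry a detectable planted effect
    expr_per_gene = pd.Series(expressed).groupby(probe_gene).sum()
    eligible = [g for g in gene_ids
                if expr_per_gene.get(g, 0) >= config.min_expressed_probes_for_effect]
    n_up = int(round(config.frac_up * config.n_genes))
    n_down = int(round(config.frac_down * config.n_genes))
    if n_up + n_down > len(eligible):
        raise ValueError("not enough eligible genes to plant the requested effects")
    chosen = rng.choice(len(eligible), size=n_up + n_down, replace=False)
    up_set = {eligible[i] for i in chosen[:n_up]}
    down_set = {eligible[i] for i in chosen[n_up:]}
    regulated = sorted(up_set | down_set)
    n_dep = int(round(config.frac_gata2_dependent * len(regulated)))
    dep_idx = rng.choice(len(regulated), size=n_dep, replace=False)
    dep_set = {regulated[i] for i in dep_idx}

    direction = np.full(config.n_genes, "none", dtype=object)
    direction[np.isin(gene_ids, list(up_set))] = "up"
    direction[np.isin(gene_ids, list(down_set))] = "down"
    dir_by_gene = dict(zip(gene_ids, direction))

    sign = np.array([{"up": 1.0, "down": -1.0, "none": 0.0}[dir_by_gene[g]]
                     for g in probe_gene])
    magnitude = np.abs(rng.normal(config.effect_log2fc, config.effect_sd, n_probes))
    effect = sign * magnitude * expressed  # only expressed probes carry effect

    dep_probe = np.array([g in dep_set for g in probe_gene])
    atten = np.where(dep_probe, 1.0 - config.dependence_attenuation, 1.0)

    if design == "stiffness_4arm":
        arms = [("ctrl-stiff", config.n_reps_ctrl, np.zeros(n_probes)),
                ("ctrl-soft", config.n_reps_ctrl, effect),
                ("kd-stiff", config.n_reps_kd, np.zeros(n_probes)),
                ("kd-soft", config.n_reps_kd, effect * atten)]
    else:
        arms = [("static", config.n_reps_ctrl, np.zeros(n_probes)),
                ("OSS", config.n_reps_ctrl, effect)]

    columns, data, design_map = [], [], {}
    for cond, n_rep, shift in arms:
        if n_rep == 0:
            continue
        for r in range(n_rep):
            sample = f"{cond}-r{r + 1}"
            columns.append(sample)
            design_map[sample] = cond
            data.append(baseline + shift + rng.normal(0.0, config.noise_sd, n_probes))
    values = pd.DataFrame(np.column_stack(data), columns=columns,
                          index=pd.MultiIndex.from_arrays(
                              [probe_ids, probe_gene],
                              names=["probe_set_id", "gene_id"]))
    truth = PlantedTruth(
        genes=pd.DataFrame({
            "gene_id": gene_ids,
            "direction": direction,
            "gata2_dependent": [g in dep_set for g in gene_ids],
        }),
        probes=pd.DataFrame({
            "probe_set_id": probe_ids,
            "gene_id": probe_gene,
            "expressed": expressed,
            "effect_log2fc": effect,
        }),
    )
    return ProbeMatrix(values, design_map), truth


@dataclass
class CurveSimConfig:
    """Parameters of a simulated force-indentation approach ramp.

    The instrument-style defaults: a 5 nN force setpoint, a scan range
    inside the 1–14 µm working envelope, 25° face-to-axis pyramid
    half-angle, incompressible sample (ν = 0.5). Forces are in nN,
    lengths in µm, moduli in kPa.
    """

    true_modulus_kPa: float = 1.0
    poisson_ratio: float = 0.5
    edge_angle_deg: float = 25.0
    angle_convention: str = "face"
    contact_z_um: float = 6.5
    baseline_offset_nN: float = 0.0
    baseline_slope_nN_per_um: float = 0.0
    noise_sd_nN: float = 0.05
    z_range_um: float = 10.0
    n_points: int = 600
    setpoint_nN: float = 5.0
    raw_mode: bool = False
    spring_constant_N_per_m: float = 0.06
    sensitivity_nm_per_V: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_modulus_kPa <= 0:
            raise ValueError("true_modulus_kPa must be > 0")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5]")
        if not 0.0 < self.edge_angle_deg < 90.0:
            raise ValueError("edge_angle_deg must be in (0, 90)")
        if not 0.0 < self.contact_z_um < self.z_range_um:
            raise ValueError("contact_z_um must lie inside the scan range")


def hertz_force(delta_um, E_kPa: float, poisson_ratio: float = 0.5,
                edge_angle_deg: float = 25.0,
                angle_convention: str = "face") -> np.ndarray:
    """Closed-form pyramid contact force (nN) at indentation δ (µm)."""
    c = pyramid_prefactor(FitParams(poisson_ratio=poisson_ratio,
                                    edge_angle_deg=edge_angle_deg,
                                    angle_convention=angle_convention))
    delta = np.clip(np.asarray(delta_um, dtype=float), 0.0, None)
    return c * E_kPa * delta * delta


def gen_force_curve(config: CurveSimConfig) -> ForceCurve:
    """Simulate one approach ramp of the pyramidal Hertz contact model.

    Piezo extension z runs from 0 toward the sample; the pre-contact
    force is the linear baseline (plus noise), past contact the Hertz
    term is added, and the ramp stops once the contact force reaches the
    setpoint. In ``raw_mode`` the stored signal is the photodiode voltage
    (deflection / sensitivity) so calibration/conversion can be tested.
    """
    rng = np.random.default_rng(config.seed)
    z = np.linspace(0.0, config.z_range_um, config.n_points)
    delta = np.clip(z - config.contact_z_um, 0.0, None)
    f_hertz = hertz_force(delta, config.true_modulus_kPa, config.poisson_ratio,
                          config.edge_angle_deg, config.angle_convention)
    over = np.nonzero(f_hertz >= config.setpoint_nN)[0]
    if over.size:
        end = over[0] + 1  # keep the first point at/above the setpoint
        z, f_hertz = z[:end], f_hertz[:end]
    baseline = config.baseline_offset_nN + config.baseline_slope_nN_per_um * z
    force = baseline + f_hertz
    if config.noise_sd_nN > 0:
        force = force + rng.normal(0.0, config.noise_sd_nN, z.size)
    meta = {"true_modulus_kPa": config.true_modulus_kPa,
            "contact_z_um": config.contact_z_um,
            "setpoint_nN": config.setpoint_nN}
    if config.raw_mode:
        k = config.spring_constant_N_per_m  # nN per nm
        volts = force / k / config.sensitivity_nm_per_V
        return ForceCurve(z=z, signal=volts, mode="deflection_V",
                          spring_constant=k,
                          sensitivity_nm_per_V=config.sensitivity_nm_per_V,
                          metadata=meta)
    return ForceCurve(z=z, signal=force, mode="force", metadata=meta)


@dataclass
class ImageSimConfig:
    """Synthetic microscopy field of elliptical cells with nuclei."""

    image_size_px: int = 256
    pixel_size_um: float = 0.5
    n_cells: int = 5
    cell_axes_px: tuple = (40.0, 28.0)  # (major, minor) semi-axes
    nucleus_axes_px: tuple = (16.0, 12.0)
    boundary_roughness: float = 0.0  # relative radial perturbation amplitude
    cell_intensity: float = 50.0
    nuclear_intensity: float = 100.0
    background_intensity: float = 10.0
    noise_sd: float = 0.0
    max_place_tries: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cell_intensity", "nuclear_intensity", "background_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nucleus_axes_px[0] > self.cell_axes_px[0] or \
                self.nucleus_axes_px[1] > self.cell_axes_px[1]:
            raise ValueError("nucleus axes must not exceed cell axes")


def _ellipse_mask(shape, center, axes, angle, roughness, rng) -> np.ndarray:
    a, b = axes
    r_max = max(a, b) * (1.0 + 2.0 * roughness) + 2
    r0 = int(max(0, math.floor(center[0] - r_max)))
    r1 = int(min(shape[0], math.ceil(center[0] + r_max) + 1))
    c0 = int(max(0, math.floor(center[1] - r_max)))
    c1 = int(min(shape[1], math.ceil(center[1] + r_max) + 1))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy, dx = rr - center[0], cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = (dx * ca + dy * sa) / a
    v = (-dx * sa + dy * ca) / b
    rho = np.hypot(u, v)
    if roughness > 0:
        phi = np.arctan2(v, u)
        modes = rng.integers(2, 6, size=3)
        amps = rng.normal(0.0, 1.0, size=3)
        amps *= roughness / max(np.sum(np.abs(amps)), 1e-12)
        phases = rng.uniform(0, 2 * math.pi, size=3)
        bound = 1.0 + sum(amp * np.cos(m * phi + ph)
                          for m, amp, ph in zip(modes, amps, phases))
    else:
        bound = 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = rho <= bound
    return mask


def gen_image(config: ImageSimConfig) -> LabeledImage:
    """Simulate a field of non-overlapping elliptical cells with nuclei.

    Returns a :class:`LabeledImage` with one intensity channel, ``cell``
    and ``nucleus`` label masks (label i = cell i), a ``background``
    mask covering every unlabeled pixel, and per-object ground truth
    (areas, noiseless integrated densities) in ``truth``. Raises if the
    requested cells cannot be placed without overlap within the retry
    budget.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.image_size_px, config.image_size_px)
    cell_labels = np.zeros(shape, dtype=np.int32)
    nuc_labels = np.zeros(shape, dtype=np.int32)
    margin = config.cell_axes_px[0] * (1.0 + 2.0 * config.boundary_roughness) + 2
    if config.n_cells > 0 and 2 * margin >= config.image_size_px:
        raise RuntimeError("cells too large for the image")
    placed = 0
    tries = 0
    truth_rows = []
    while placed < config.n_cells:
        if tries >= config.max_place_tries:
            raise RuntimeError(
                f"could not place {config.n_cells} non-overlapping cells "
                f"within {config.max_place_tries} tries")
        tries += 1
        center = rng.uniform(margin, config.image_size_px - margin, size=2)
        angle = rng.uniform(0, math.pi)
        cmask = _ellipse_mask(shape, center, config.cell_axes_px, angle,
                              config.boundary_roughness, rng)
        if (cell_labels[cmask] != 0).any():
            continue
        placed += 1
        cell_labels[cmask] = placed
        nmask = _ellipse_mask(shape, center, config.nucleus_axes_px, angle,
                              config.boundary_roughness, rng)
        nmask &= cmask  # nuclei lie inside their cells
        nuc_labels[nmask] = placed
        truth_rows.append({"object_id": placed,
                           "center": tuple(center), "angle": angle,
                           "cell_area_px": int(cmask.sum()),
                           "nucleus_area_px": int(nmask.sum())})
    background = (cell_labels == 0).astype(np.int32)
    image = np.full(shape, config.background_intensity, dtype=float)
    image[cell_labels > 0] = config.cell_intensity
    image[nuc_labels > 0] = config.nuclear_intensity
    for row in truth_rows:
        sel = cell_labels == row["object_id"]
        row["integrated_density"] = float(image[sel].sum())
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, shape)
    return LabeledImage(
        channels={"intensity": image},
        masks={"cell": cell_labels, "nucleus": nuc_labels,
               "background": background},
        pixel_size_um=config.pixel_size_um,
        truth={"objects": truth_rows,
               "background_intensity": config.background_intensity,
               "cell_intensity": config.cell_intensity,
               "nuclear_intensity": config.nuclear_intensity},
    )
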