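"""Synthetic two-group layered-hippocampus studies.

The phantom replaces ex-vivo data: a schematic slab of parallel bands (one
band per hippocampal subregion/layer), per-subject neurite densities drawn
from group-level mean/SD, signals from the forward model, and Rician noise.

The default layer table carries the published group-level neurite densities
(mean +- SD, n = 4 per group) for the ten subregions: CA1 and CA3 stratum
oriens (SO), pyramidal cell layer (CL), stratum radiatum (SR) and stratum
lacunosum-moleculare (LM), plus the dentate gyrus granule cell (GL) and
molecular (ML) layers. Cell-body layers (CL, GL) use an isotropic ODF; the
dendritic layers use a coherent (Watson) ODF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import AcquisitionScheme, DWIVolume, LabelMap, default_scheme
from .forward import TissueParams, isotropic_odf_coeffs, predict_signal, watson_odf_coeffs

__all__ = [
    "LayerSpec",
    "Geometry",
    "StudyDesign",
    "PhantomStudy",
    "GROUPS",
    "LAYER_TYPES",
    "TABLE1_DENSITIES",
    "default_layers",
    "six_layer_specs",
    "make_labelmap",
    "add_rician_noise",
    "simulate_subject",
    "simulate_study",
]

GROUPS = ("stressed", "control")
LAYER_TYPES = ("SO", "CL", "SR", "LM", "GL", "ML")

#: Published per-subregion neurite density (mean, SD) for each group,
#: keyed by (region, layer). n = 4 subjects per group.
TABLE1_DENSITIES: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("CA1", "SO"): {"stressed": (0.27, 0.03), "control": (0.40, 0.10)},
    ("CA1", "CL"): {"stressed": (0.24, 0.05), "control": (0.33, 0.05)},
    ("CA1", "SR"): {"stressed": (0.26, 0.02), "control": (0.39, 0.06)},
    ("CA1", "LM"): {"stressed": (0.31, 0.05), "control": (0.41, 0.04)},
    ("CA3", "SO"): {"stressed": (0.36, 0.06), "control": (0.41, 0.12)},
    ("CA3", "CL"): {"stressed": (0.30, 0.03), "control": (0.32, 0.06)},
    ("CA3", "SR"): {"stressed": (0.33, 0.03), "control": (0.43, 0.07)},
    ("CA3", "LM"): {"stressed": (0.31, 0.03), "control": (0.41, 0.05)},
    ("DG", "GL"): {"stressed": (0.23, 0.005), "control": (0.31, 0.04)},
    ("DG", "ML"): {"stressed": (0.28, 0.03), "control": (0.36, 0.03)},
}

# fixed-tissue defaults, mm^2/s
_D_LONG = 1.2e-3
_D_TRANS = 0.1e-3
_D_EFF = 0.7e-3
_WATSON_KAPPA = 4.0  # l_max=4 truncation of the Watson ODF stays nonnegative


@dataclass(frozen=True)
class LayerSpec:
    """Ground-truth description of one simulated layer."""

    name: str  # one of LAYER_TYPES
    nu_mean: dict[str, float]  # per group
    nu_sd: dict[str, float]  # per group
    region: str = ""  # optional CA1/CA3/DG prefix
    d_eff: float = _D_EFF
    d_long: float = _D_LONG
    d_trans: float = _D_TRANS
    odf_mode: str = "coherent"  # "coherent" | "isotropic"
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.name not in LAYER_TYPES:
            raise ValueError(f"unknown layer type {self.name!r}")
        if self.odf_mode not in ("coherent", "isotropic"):
            raise ValueError(f"unknown odf_mode {self.odf_mode!r}")
        for group in self.nu_mean:
            m, sd = self.nu_mean[group], self.nu_sd[group]
            if not (0.0 <= m - 3 * sd and m + 3 * sd <= 1.0):
                raise ValueError(
                    f"{self.key}/{group}: nu_mean +- 3*nu_sd must lie within [0, 1]"
                )

    @property
    def key(self) -> str:
        """Label-map name, e.g. ``CA3_SR`` or bare ``SR``."""
        return f"{self.region}_{self.name}" if self.region else self.name

    def odf_coeffs(self, l_max: int = 4) -> np.ndarray:
        if self.odf_mode == "isotropic":
            return isotropic_odf_coeffs(l_max)
        return watson_odf_coeffs(np.asarray(self.axis), _WATSON_KAPPA, l_max)


def default_layers() -> list[LayerSpec]:
    """The ten published subregions with their group means/SDs.

    Cell-body layers (CL, GL) are isotropic with the second compartment
    standing in for somas plus extracellular space; the rest are coherent.
    """
    layers = []
    for (region, name), groups in TABLE1_DENSITIES.items():
        layers.append(
            LayerSpec(
                name=name,
                region=region,
                nu_mean={g: groups[g][0] for g in GROUPS},
                nu_sd={g: groups[g][1] for g in GROUPS},
                odf_mode="isotropic" if name in ("CL", "GL") else "coherent",
            )
        )
    return layers


def six_layer_specs() -> list[LayerSpec]:
    """One band per layer type (SO, CL, SR, LM, GL, ML), CA3/DG values."""
    specs = []
    for name in LAYER_TYPES:
        region = "DG" if name in ("GL", "ML") else "CA3"
        groups = TABLE1_DENSITIES[(region, name)]
        specs.append(
            LayerSpec(
                name=name,
                nu_mean={g: groups[g][0] for g in GROUPS},
                nu_sd={g: groups[g][1] for g in GROUPS},
                odf_mode="isotropic" if name in ("CL", "GL") else "coherent",
            )
        )
    return specs


@dataclass(frozen=True)
class Geometry:
    """Layered 2-D slab template: parallel bands, one per layer key.

    Doubling ``band_width`` exactly doubles every layer's voxel count.
    """

    layer_keys: tuple[str, ...]
    band_width: int = 2
    n_cols: int = 16
    margin: int = 1  # background rows framing the slab
    slab_thickness: int = 1

    def __post_init__(self) -> None:
        if self.band_width < 1 or self.n_cols < 1 or self.slab_thickness < 1:
            raise ValueError("geometry must give every layer at least one voxel")
        if not self.layer_keys:
            raise ValueError("geometry needs at least one layer")

    @property
    def shape(self) -> tuple[int, int, int]:
        n_rows = len(self.layer_keys) * self.band_width + 2 * self.margin
        return (n_rows, self.n_cols, self.slab_thickness)


def make_labelmap(geometry: Geometry) -> LabelMap:
    """Deterministic banded label map; labels 1..n in layer order."""
    labels = np.zeros(geometry.shape, dtype=np.int32)
    names = {}
    for i, key in enumerate(geometry.layer_keys):
        r0 = geometry.margin + i * geometry.band_width
        labels[r0 : r0 + geometry.band_width, :, :] = i + 1
        names[i + 1] = key
    return LabelMap(labels=labels, names=names)


@dataclass(frozen=True)
class StudyDesign:
    """Two-group study layout and noise model."""

    n_per_group: int = 4
    snr_b0: float = 50.0  # math.inf -> noise-free
    seed: int = 0
    scheme: AcquisitionScheme = field(default_factory=default_scheme)
    geometry: Geometry | None = None  # default: ten-band published layout

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if not self.snr_b0 > 0:
            raise ValueError("snr_b0 must be positive (math.inf for noise-free)")


def _resolve_geometry(layers: list[LayerSpec], design: StudyDesign) -> Geometry:
    keys = tuple(spec.key for spec in layers)
    if design.geometry is not None:
        if design.geometry.layer_keys != keys:
            raise ValueError("geometry layer_keys must match the layer specs in order")
        return design.geometry
    return Geometry(layer_keys=keys)


def add_rician_noise(
    signal: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Magnitude (Rician) noise: sqrt((S + e1)^2 + e2^2), e ~ N(0, sigma).

    For S = 0 the observed magnitude is Rayleigh with mean sigma*sqrt(pi/2).
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    e1 = rng.normal(0.0, sigma, np.shape(signal))
    e2 = rng.normal(0.0, sigma, np.shape(signal))
    return np.sqrt((signal + e1) ** 2 + e2**2)


def _draw_truncated_nu(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw rejected outside [0, 1] (SDs here make rejection rare)."""
    if sd == 0:
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if 0.0 <= v <= 1.0:
            return float(v)
    raise RuntimeError("truncated-normal rejection failed")  # pragma: no cover


def simulate_subject(
    layers: list[LayerSpec],
    group: str,
    design: StudyDesign,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[DWIVolume, dict[str, float]]:
    """Simulate one subject: draw per-layer nu, fill voxels, add Rician noise.

    Returns the noisy volume and the subject's ground-truth ``{layer: nu}``.
    Noise: observed = sqrt((S + e1)^2 + e2^2) with e ~ N(0, sigma),
    sigma = s0 / snr_b0 / sqrt(n_averages).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    geometry = _resolve_geometry(layers, design)
    labelmap = make_labelmap(geometry)
    rng = np.random.default_rng(design.seed if seed is None else seed)
    signal = np.zeros(geometry.shape + (len(design.scheme),))
    truth: dict[str, float] = {}
    s0 = 1.0
    for label, spec in zip(labelmap.label_values, layers):
        nu = _draw_truncated_nu(rng, spec.nu_mean[group], spec.nu_sd[group])
        truth[spec.key] = nu
        params = TissueParams(
            s0=s0,
            nu=nu,
            d_eff=spec.d_eff,
            d_long=spec.d_long,
            d_trans=spec.d_trans,
            odf_coeffs=spec.odf_coeffs(),
        )
        signal[labelmap.labels == label] = predict_signal(params, design.scheme)
    if math.isfinite(design.snr_b0):
        sigma = s0 / design.snr_b0 / math.sqrt(design.scheme.n_averages)
        signal = add_rician_noise(signal, sigma, rng)
    vol = DWIVolume(signal=signal, scheme=design.scheme)
    return vol, truth


@dataclass(frozen=True)
class PhantomStudy:
    """Two groups of simulated volumes with shared labels and ground truth."""

    volumes: dict[str, list[DWIVolume]]
    labelmap: LabelMap
    ground_truth: pd.DataFrame  # columns: subject, group, roi, nu
    design: StudyDesign
    layers: tuple[LayerSpec, ...]

    @property
    def subjects(self) -> list[tuple[str, str]]:
        return [
            (f"{g}{i + 1:02d}", g)
            for g in GROUPS
            for i in range(len(self.volumes[g]))
        ]


def simulate_study(layers: list[LayerSpec] | None = None, design: StudyDesign | None = None) -> PhantomStudy:
    """Simulate the full two-group study with per-subject derived seeds."""
    layers = default_layers() if layers is None else layers
    design = design or StudyDesign()
    geometry = _resolve_geometry(layers, design)
    labelmap = make_labelmap(geometry)
    children = np.random.SeedSequence(design.seed).spawn(2 * design.n_per_group)
    volumes: dict[str, list[DWIVolume]] = {g: [] for g in GROUPS}
    rows = []
    for gi, group in enumerate(GROUPS):
        for i in range(design.n_per_group):
            seed = children[gi * design.n_per_group + i]
            vol, truth = simulate_subject(layers, group, design, seed=seed)
            volumes[group].append(vol)
            subject = f"{group}{i + 1:02d}"
            for roi, nu in truth.items():
                rows.append({"subject": subject, "group": group, "roi": roi, "nu": nu})
    ground_truth = pd.DataFrame(rows)
    return PhantomStudy(
        volumes=volumes,
        labelmap=labelmap,
        ground_truth=ground_truth,
        design=design,
        layers=tuple(layers),
    )
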