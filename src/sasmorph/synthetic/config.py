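"""Scenario configuration for synthetic neuropil volumes.

Defaults encode the study conditions of the published human
transentorhinal-cortex dataset this package re-analyses: 5 x 5 x 20 nm
voxels (5 nm/pixel in-plane, 20 nm FIB/SEM section thickness), an AS:SS
ratio of ~95:5, and per-type postsynaptic-target and shape mixes taken
from the published control count tables.  Geometric parameters (dendrite
radii, spine dimensions, synapse packing density) are the package's own
realism choices: only the class structure, not the true tissue geometry,
is knowable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

TARGET_CLASSES = ("spine_head", "spine_neck", "aspiny_shaft", "spiny_shaft")
SHAPE_CLASSES = ("macular", "perforated", "horseshoe", "fragmented")
SYNAPSE_TYPES = ("AS", "SS")

# control-group mixes from the published count tables
_DEFAULT_TARGET_MIX = {
    "AS": (825 / 1396, 7 / 1396, 278 / 1396, 286 / 1396),
    "SS": (8 / 112, 1 / 112, 43 / 112, 60 / 112),
}
_DEFAULT_SHAPE_MIX = {
    "AS": (2145 / 2561, 302 / 2561, 98 / 2561, 16 / 2561),
    "SS": (106 / 127, 5 / 127, 16 / 127, 0.0),
}

# log-area distributions (nm^2) per shape class; means follow the
# published right-skewed size pattern (macular smallest, fragmented
# largest), family log-normal as assumed from the frequency histograms
_DEFAULT_AREA_LOGNORMAL = {
    "macular": (11.25, 0.35),
    "perforated": (12.36, 0.35),
    "horseshoe": (12.35, 0.35),
    "fragmented": (12.66, 0.35),
}

#: PSD slab thickness by type, nm.  At 20 nm section thickness a thin
#: (symmetric) density spans one section and a prominent (asymmetric)
#: one spans two, so the defaults are one and two section pitches.
_DEFAULT_PSD_THICKNESS = {"AS": 40.0, "SS": 20.0}


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic neuropil stack.

    ``volume_shape`` is (nx, ny, nz) voxels; ``voxel_size_nm`` is
    (dx, dy, dz) in nm.  ``synapse_density`` is junctions per um^3 of
    stack volume.  ``target_mix`` and ``shape_mix`` are probability
    vectors per synapse type over :data:`TARGET_CLASSES` /
    :data:`SHAPE_CLASSES`.  ``edge_margin_nm`` keeps junction anchors
    away from the stack borders so that most objects are unbroken;
    set to 0 to emulate heavily truncated stacks.
    """

    volume_shape: tuple[int, int, int] = (512, 512, 128)
    voxel_size_nm: tuple[float, float, float] = (5.0, 5.0, 20.0)
    n_dendrites: int = 12
    spines_per_micron: float = 0.6
    fraction_aspiny_dendrites: float = 0.5
    synapse_density: float = 6.0
    as_fraction: float = 0.95
    target_mix: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in
                                 _DEFAULT_TARGET_MIX.items()})
    shape_mix: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in
                                 _DEFAULT_SHAPE_MIX.items()})
    sas_area_lognormal: dict = field(
        default_factory=lambda: dict(_DEFAULT_AREA_LOGNORMAL))
    psd_thickness_nm: dict = field(
        default_factory=lambda: dict(_DEFAULT_PSD_THICKNESS))
    edge_margin_nm: float = 400.0
    multi_synapse_head_fraction: float = 0.05
    max_retries: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.volume_shape) != 3 or min(self.volume_shape) < 1:
            raise ValueError("volume_shape must be three positive ints")
        if len(self.voxel_size_nm) != 3 or min(self.voxel_size_nm) <= 0:
            raise ValueError("voxel_size_nm must be strictly positive")
        if not 0 <= self.as_fraction <= 1:
            raise ValueError("as_fraction must be in [0, 1]")
        if not 0 <= self.fraction_aspiny_dendrites <= 1:
            raise ValueError("fraction_aspiny_dendrites must be in [0, 1]")
        if self.synapse_density < 0:
            raise ValueError("synapse_density must be >= 0")
        for name, mix, keys in (
            ("target_mix", self.target_mix, TARGET_CLASSES),
            ("shape_mix", self.shape_mix, SHAPE_CLASSES),
        ):
            for typ in SYNAPSE_TYPES:
                vec = mix.get(typ)
                if vec is None or len(vec) != len(keys):
                    raise ValueError(
                        f"{name}[{typ}] must have {len(keys)} entries")
                if any(p < 0 for p in vec):
                    raise ValueError(f"{name}[{typ}] has negative entries")
                if abs(sum(vec) - 1.0) > 1e-9:
                    raise ValueError(f"{name}[{typ}] must sum to 1")
        for shape in SHAPE_CLASSES:
            if shape not in self.sas_area_lognormal:
                raise ValueError(f"missing area distribution for {shape}")
        for typ in SYNAPSE_TYPES:
            if self.psd_thickness_nm.get(typ, 0) <= 0:
                raise ValueError("psd_thickness_nm must be positive per type")

    # -- convenience ------------------------------------------------------

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        nx, ny, nz = self.volume_shape
        dx, dy, dz = self.voxel_size_nm
        return (nx * dx, ny * dy, nz * dz)

    @property
    def volume_um3(self) -> float:
        ex, ey, ez = self.extent_nm
        return ex * ey * ez * 1e-9

    @property
    def n_synapses(self) -> int:
        return int(round(self.synapse_density * self.volume_um3))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("volume_shape", "voxel_size_nm"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("target_mix", "shape_mix", "sas_area_lognormal"):
            if key in d:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        return cls(**d)
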