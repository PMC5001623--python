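"""Synthetic benchmarks under the additive image-formation model.

Scenes are collections of circles/ellipses on a flat background; the
noiseless image is mu_minus + n(x) * delta_mu where n(x) counts the
shapes covering pixel x, so stacked objects are brighter in proportion
to their multiplicity.  Gaussian white noise is added at a prescribed
SNR, with signal power defined as the spatial variance of the noiseless
image (at 0 dB noise and signal have equal power).  Rasterization is
binary — a pixel belongs to a shape iff its centre does — which makes
area bookkeeping exact and ground truth unambiguous.

Five ready-made suites reproduce the benchmark families used to probe
size selectivity, initialization dependence, noise robustness,
overlap separation, and ellipticity tolerance; their geometry, intensity
levels and noise defaults are documented per suite in ``SUITE_DEFAULTS``
and every count is overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .extraction import InstanceSet
from .intensity import ImageFormationParams

__all__ = [
    "ShapeInstance",
    "SceneSpec",
    "GenerationError",
    "rasterize_shape",
    "sample_scene",
    "render_clean",
    "add_noise_snr",
    "scene_ground_truth",
    "generate_suite",
    "SUITE_NAMES",
    "SUITE_DEFAULTS",
]


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ShapeInstance:
    """A circle or axis-oriented ellipse in pixel coordinates."""

    kind: str  # 'circle' | 'ellipse'
    center: tuple  # (x, y)
    radii: tuple  # (r,) or (r_minor, r_major)
    orientation: float = 0.0  # radians, major axis vs +x (ellipses)

    def __post_init__(self):
        if self.kind not in ("circle", "ellipse"):
            raise ValueError("kind must be 'circle' or 'ellipse'")
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")
        if self.kind == "ellipse" and self.radii[0] > self.radii[1]:
            raise ValueError("expect (r_minor, r_major) with r_minor <= r_major")

    @property
    def max_extent(self) -> float:
        return max(self.radii)

    def area(self) -> float:
        if self.kind == "circle":
            return math.pi * self.radii[0] ** 2
        return math.pi * self.radii[0] * self.radii[1]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "center": list(self.center),
            "radii": list(self.radii),
            "orientation": self.orientation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShapeInstance":
        return cls(
            kind=d["kind"],
            center=tuple(d["center"]),
            radii=tuple(d["radii"]),
            orientation=float(d.get("orientation", 0.0)),
        )


@dataclass
class SceneSpec:
    """One synthetic scene: geometry, intensities, noise, seed."""

    size: tuple  # (H, W)
    shapes: list
    imaging: ImageFormationParams
    snr_db: float | None = None
    max_overlap: float = 0.0
    rng_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "size": list(self.size),
            "shapes": [s.to_dict() for s in self.shapes],
            "imaging": {
                "mu_minus": self.imaging.mu_minus,
                "sigma2_minus": self.imaging.sigma2_minus,
                "delta_mu": self.imaging.delta_mu,
                "delta_sigma2": self.imaging.delta_sigma2,
            },
            "snr_db": self.snr_db,
            "max_overlap": self.max_overlap,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        return cls(
            size=tuple(d["size"]),
            shapes=[ShapeInstance.from_dict(s) for s in d["shapes"]],
            imaging=ImageFormationParams(**d["imaging"]),
            snr_db=d.get("snr_db"),
            max_overlap=float(d.get("max_overlap", 0.0)),
            rng_seed=int(d.get("rng_seed", 0)),
        )


def rasterize_shape(shape: ShapeInstance, size) -> np.ndarray:
    """Binary coverage mask: pixel centre inside (or on) the shape."""
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = shape.center
    dx = xx - cx
    dy = yy - cy
    if shape.kind == "circle":
        return dx * dx + dy * dy <= shape.radii[0] ** 2
    rmin, rmaj = shape.radii
    ct, st = math.cos(shape.orientation), math.sin(shape.orientation)
    u = dx * ct + dy * st  # along major axis
    v = -dx * st + dy * ct
    return (u / rmaj) ** 2 + (v / rmin) ** 2 <= 1.0


_DEFAULT_IMAGING = ImageFormationParams(
    mu_minus=40.0, sigma2_minus=1.0, delta_mu=60.0, delta_sigma2=0.0
)


def sample_scene(
    n: int,
    shape_template: ShapeInstance,
    size,
    max_overlap: float,
    rng: np.random.Generator,
    *,
    imaging: ImageFormationParams = _DEFAULT_IMAGING,
    snr_db: float | None = None,
    max_rejects: int = 100_000,
    rng_seed: int = 0,
) -> SceneSpec:
    """Place n shapes by uniform rejection sampling.

    Centres are uniform over positions keeping the shape fully inside
    the image; orientations (ellipses) uniform over [0, pi).  A proposal
    is rejected when any pairwise rasterized intersection would exceed
    max_overlap times the smaller shape's rasterized area.  Fails after
    ``max_rejects`` rejected proposals.
    """
    if not (0.0 <= max_overlap <= 1.0):
        raise ValueError("max_overlap must be in [0, 1]")
    h, w = size
    ext = shape_template.max_extent
    if 2 * ext >= min(h, w):
        raise GenerationError("shape does not fit inside the image")
    placed_masks: list[np.ndarray] = []
    placed_areas: list[int] = []
    shapes: list[ShapeInstance] = []
    rejects = 0
    while len(shapes) < n:
        cx = rng.uniform(ext, w - 1 - ext)
        cy = rng.uniform(ext, h - 1 - ext)
        theta = rng.uniform(0.0, math.pi) if shape_template.kind == "ellipse" else 0.0
        cand = ShapeInstance(
            kind=shape_template.kind,
            center=(cx, cy),
            radii=shape_template.radii,
            orientation=theta,
        )
        mask = rasterize_shape(cand, size)
        area = int(mask.sum())
        ok = True
        for m, a in zip(placed_masks, placed_areas):
            inter = int(np.count_nonzero(mask & m))
            if inter > max_overlap * min(area, a):
                ok = False
                break
        if ok:
            shapes.append(cand)
            placed_masks.append(mask)
            placed_areas.append(area)
        else:
            rejects += 1
            if rejects >= max_rejects:
                raise GenerationError(
                    f"could not place {n} shapes with max_overlap={max_overlap} "
                    f"in a {h}x{w} image after {max_rejects} rejections"
                )
    return SceneSpec(
        size=tuple(size),
        shapes=shapes,
        imaging=imaging,
        snr_db=snr_db,
        max_overlap=max_overlap,
        rng_seed=rng_seed,
    )


def coverage_count(scene: SceneSpec) -> np.ndarray:
    count = np.zeros(scene.size, dtype=np.int32)
    for s in scene.shapes:
        count += rasterize_shape(s, scene.size)
    return count


def render_clean(scene: SceneSpec) -> np.ndarray:
    """Noiseless additive image: mu_minus + coverage * delta_mu."""
    return scene.imaging.mu_minus + coverage_count(scene) * scene.imaging.delta_mu


def add_noise_snr(
    clean: np.ndarray, snr_db: float, rng: np.random.Generator
) -> np.ndarray:
    """Add white Gaussian noise at the requested SNR.

    Noise variance is Var(clean) / 10^(snr_db/10) with Var(clean) the
    spatial variance of the noiseless image (its AC signal power, so the
    flat background offset does not inflate the nominal SNR).  Output
    stays floating point; no quantization.
    """
    clean = np.asarray(clean, dtype=float)
    signal_power = float(np.var(clean))
    if signal_power == 0.0:
        raise ValueError("constant image has zero signal power")
    sigma = math.sqrt(signal_power / 10.0 ** (snr_db / 10.0))
    return clean + rng.normal(0.0, sigma, size=clean.shape)


def noise_variance(scene: SceneSpec) -> float:
    """Variance of the noise that add_noise_snr applies to this scene."""
    if scene.snr_db is None:
        return 0.0
    return float(np.var(render_clean(scene))) / 10.0 ** (scene.snr_db / 10.0)


def render_scene(scene: SceneSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Clean render plus the scene's noise (if any)."""
    clean = render_clean(scene)
    if scene.snr_db is None:
        return clean
    if rng is None:
        rng = np.random.default_rng(scene.rng_seed)
    return add_noise_snr(clean, scene.snr_db, rng)


def scene_ground_truth(scene: SceneSpec) -> InstanceSet:
    """Layered instance masks: overlapping shapes go to different layers
    (greedy colouring of the rasterized-overlap graph)."""
    masks = [rasterize_shape(s, scene.size) for s in scene.shapes]
    n = len(masks)
    layer_of = [-1] * n
    order = range(n)
    for i in order:
        used = {
            layer_of[j]
            for j in range(n)
            if layer_of[j] >= 0 and bool(np.any(masks[i] & masks[j]))
        }
        c = 0
        while c in used:
            c += 1
        layer_of[i] = c
    out = InstanceSet(grid_shape=tuple(scene.size))
    out.masks = masks
    out.layer_of = layer_of
    return out


SUITE_NAMES = (
    "two_radius",
    "noise_ladder",
    "triangle_series",
    "ellipse_series",
    "init_benchmark",
)

# Full-scale defaults; every entry can be overridden via generate_suite(**kw).
SUITE_DEFAULTS: dict = {
    "two_radius": dict(
        n_images=5,
        size=(200, 200),
        n_large=5,
        r_large=15.0,
        n_small=5,
        r_small=5.0,
        max_overlap=0.1,
        snr_db=10.0,
        mu_minus=40.0,
        delta_mu=60.0,
    ),
    "noise_ladder": dict(
        n_images_per_level=50,
        snr_levels=(20.0, 15.0, 10.0, 5.0, 0.0, -5.0),
        size=(400, 400),
        n_circles=15,
        radius=15.0,
        max_overlap=0.2,
        mu_minus=40.0,
        delta_mu=60.0,
    ),
    "triangle_series": dict(
        ratios=tuple(np.round(np.arange(0.0, 4.01, 0.25), 2)),
        radius=15.0,
        size=(170, 170),
        snr_db=0.0,
        mu_minus=40.0,
        delta_mu=60.0,
    ),
    "ellipse_series": dict(
        n_images_per_ratio=100,
        r_minor=10.0,
        r_major_values=tuple(range(11, 26)),
        n_ellipses=5,
        size=(150, 150),
        max_overlap=0.1,
        snr_db=10.0,
        mu_minus=40.0,
        delta_mu=60.0,
    ),
    "init_benchmark": dict(
        n_images_per_count_large=20,
        counts_large=(30, 35, 40),
        size_large=(400, 400),
        n_images_per_count_small=20,
        counts_small=(4, 5, 6, 7, 8, 9, 10),
        size_small=(150, 150),
        radius=15.0,
        max_overlap=1.0,
        snr_db=10.0,
        backgrounds=(30.0, 40.0, 50.0),
        foregrounds=(90.0, 100.0, 110.0),
    ),
}


def _finalize(scene: SceneSpec, rng: np.random.Generator):
    """Attach the realised noise variance to the imaging parameters and
    render the (noisy) image."""
    var = noise_variance(scene)
    scene.imaging = ImageFormationParams(
        mu_minus=scene.imaging.mu_minus,
        sigma2_minus=var if var > 0 else 1.0,
        delta_mu=scene.imaging.delta_mu,
        delta_sigma2=0.0,
    )
    clean = render_clean(scene)
    image = clean if scene.snr_db is None else add_noise_snr(clean, scene.snr_db, rng)
    return image, scene_ground_truth(scene), scene


def _imaging(mu_minus, delta_mu):
    return ImageFormationParams(
        mu_minus=float(mu_minus), sigma2_minus=1.0, delta_mu=float(delta_mu)
    )


def generate_suite(name: str, rng, out_dir=None, **overrides):
    """Generate one benchmark suite.

    Returns a list of records ``{"image", "truth", "scene", "tag"}``;
    with ``out_dir`` given, also writes <tag>_image.tif (16-bit),
    <tag>_truth.tif (multi-page 16-bit label stack) and
    <tag>_scene.json per image.

    ``rng`` may be a Generator or an integer seed.  Unknown override
    keys raise, so typos cannot silently change a suite.
    """
    if name not in SUITE_NAMES:
        raise ValueError(f"unknown suite {name!r}; expected one of {SUITE_NAMES}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    params = dict(SUITE_DEFAULTS[name])
    unknown = set(overrides) - set(params)
    if unknown:
        raise ValueError(f"unknown overrides for suite {name!r}: {sorted(unknown)}")
    params.update(overrides)
    records = list(_SUITE_BUILDERS[name](params, rng))
    if out_dir is not None:
        from . import io as mio

        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in records:
            tag = rec["tag"]
            mio.write_image(out / f"{tag}_image.tif", rec["image"])
            mio.write_label_stack(rec["truth"], out / f"{tag}_truth.tif")
            (out / f"{tag}_scene.json").write_text(
                json.dumps(rec["scene"].to_dict(), indent=1)
            )
    return records


def _gen_two_radius(p, rng):
    tmpl_large = ShapeInstance("circle", (0, 0), (p["r_large"],))
    tmpl_small = ShapeInstance("circle", (0, 0), (p["r_small"],))
    for i in range(p["n_images"]):
        seed = int(rng.integers(2**31))
        r = np.random.default_rng(seed)
        scene = sample_scene(
            p["n_large"], tmpl_large, p["size"], p["max_overlap"], r,
            imaging=_imaging(p["mu_minus"], p["delta_mu"]),
            snr_db=p["snr_db"], rng_seed=seed,
        )
        # add the small circles against the already placed large ones
        small = sample_scene(
            p["n_small"], tmpl_small, p["size"], p["max_overlap"], r,
            imaging=scene.imaging, snr_db=p["snr_db"], rng_seed=seed,
        )
        merged: list[ShapeInstance] = list(scene.shapes)
        size = p["size"]
        masks = [rasterize_shape(s, size) for s in merged]
        for cand in small.shapes:
            m = rasterize_shape(cand, size)
            a = int(m.sum())
            if all(
                np.count_nonzero(m & mm) <= p["max_overlap"] * min(a, int(mm.sum()))
                for mm in masks
            ):
                merged.append(cand)
                masks.append(m)
        scene.shapes = merged
        image, truth, scene = _finalize(scene, r)
        yield {"image": image, "truth": truth, "scene": scene, "tag": f"two_radius_{i:03d}"}


def _gen_noise_ladder(p, rng):
    tmpl = ShapeInstance("circle", (0, 0), (p["radius"],))
    for snr in p["snr_levels"]:
        for i in range(p["n_images_per_level"]):
            seed = int(rng.integers(2**31))
            r = np.random.default_rng(seed)
            scene = sample_scene(
                p["n_circles"], tmpl, p["size"], p["max_overlap"], r,
                imaging=_imaging(p["mu_minus"], p["delta_mu"]),
                snr_db=float(snr), rng_seed=seed,
            )
            image, truth, scene = _finalize(scene, r)
            tag = f"noise_{snr:+05.1f}dB_{i:03d}".replace(".", "p")
            yield {"image": image, "truth": truth, "scene": scene, "tag": tag}


def _gen_triangle(p, rng):
    rad = p["radius"]
    h, w = p["size"]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    for ratio in p["ratios"]:
        seed = int(rng.integers(2**31))
        r = np.random.default_rng(seed)
        wdist = ratio * rad  # centre-to-centre distance
        circ = wdist / math.sqrt(3.0)  # circumradius of the triangle
        shapes = [
            ShapeInstance(
                "circle",
                (cx + circ * math.cos(a), cy + circ * math.sin(a)),
                (rad,),
            )
            for a in (math.pi / 2, math.pi / 2 + 2 * math.pi / 3, math.pi / 2 + 4 * math.pi / 3)
        ]
        scene = SceneSpec(
            size=p["size"], shapes=shapes,
            imaging=_imaging(p["mu_minus"], p["delta_mu"]),
            snr_db=p["snr_db"], max_overlap=1.0, rng_seed=seed,
        )
        image, truth, scene = _finalize(scene, r)
        tag = f"triangle_w{ratio:4.2f}r".replace(".", "p")
        yield {"image": image, "truth": truth, "scene": scene, "tag": tag}


def _gen_ellipse(p, rng):
    for rmaj in p["r_major_values"]:
        tmpl = ShapeInstance("ellipse", (0, 0), (p["r_minor"], float(rmaj)))
        for i in range(p["n_images_per_ratio"]):
            seed = int(rng.integers(2**31))
            r = np.random.default_rng(seed)
            scene = sample_scene(
                p["n_ellipses"], tmpl, p["size"], p["max_overlap"], r,
                imaging=_imaging(p["mu_minus"], p["delta_mu"]),
                snr_db=p["snr_db"], rng_seed=seed,
            )
            image, truth, scene = _finalize(scene, r)
            yield {
                "image": image, "truth": truth, "scene": scene,
                "tag": f"ellipse_rmax{int(rmaj):02d}_{i:03d}",
            }


def _gen_init_benchmark(p, rng):
    tmpl = ShapeInstance("circle", (0, 0), (p["radius"],))
    blocks = [
        ("large", p["size_large"], p["counts_large"], p["n_images_per_count_large"]),
        ("small", p["size_small"], p["counts_small"], p["n_images_per_count_small"]),
    ]
    for label, size, counts, reps in blocks:
        for count in counts:
            for i in range(reps):
                seed = int(rng.integers(2**31))
                r = np.random.default_rng(seed)
                bg = float(r.choice(p["backgrounds"]))
                fg = float(r.choice(p["foregrounds"]))
                scene = sample_scene(
                    int(count), tmpl, size, p["max_overlap"], r,
                    imaging=_imaging(bg, fg - bg),
                    snr_db=p["snr_db"], rng_seed=seed,
                )
                image, truth, scene = _finalize(scene, r)
                yield {
                    "image": image, "truth": truth, "scene": scene,
                    "tag": f"init_{label}_n{int(count):02d}_{i:03d}",
                }


_SUITE_BUILDERS = {
    "two_radius": _gen_two_radius,
    "noise_ladder": _gen_noise_ladder,
    "triangle_series": _gen_triangle,
    "ellipse_series": _gen_ellipse,
    "init_benchmark": _gen_init_benchmark,
}
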