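"""Synthetic disc-centered fundus scenes with exact ground truth.

The generator emulates the structures the morphometry pipeline measures:
recursive bifurcating artery/vein trees rooted at the optic disc border,
Murray-law caliber taper at every bifurcation, sinusoidal centerline
perturbation with a closed-form arc/chord ratio, and a bright disc/cup pair
on a vignetted background.  Every scene carries its ground truth: exact
stamped masks, the generating graph, and per-segment / per-bifurcation truth
tables, so downstream stages can be scored against known values.

Cohorts mirror a two-group (highland vs. lowland children) design: group
effects are injected at the truth level (caliber, branching angle, disc and
cup size), covariates are drawn from group-specific distributions, and both
eyes of a subject share the subject's covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .geometry import Ellipse, circle
from .graph import Node, Segment, VesselGraph
from .segmentation import FundusImage

__all__ = [
    "TreeSpec",
    "DiscSpec",
    "CohortSpec",
    "GroundTruth",
    "generate_tree",
    "render_fundus",
    "default_scene",
    "build_scene",
    "draw_cohort_parameters",
    "generate_cohort",
    "disc_to_ellipse",
]


# ----------------------------------------------------------------- specs


@dataclass(frozen=True)
class TreeSpec:
    """Parameters of one recursive bifurcating vessel tree.

    Calibers are vessel *diameters* in pixels.  ``taper_exponent`` is the
    Murray-law exponent e with parent^e = sum(child^e) at every bifurcation.
    ``split_ratio`` is the daughter diameter ratio (thin/thick); 1.0 gives a
    symmetric split.  Tortuosity is synthesized as a raised-cosine lateral
    offset with zero displacement and zero slope at both segment ends, so
    each segment's true arc/chord ratio has a closed form and daughter
    chord directions equal the local tangents at bifurcations.
    """

    trunk_caliber_artery: float = 12.0  # px
    trunk_caliber_vein: float = 15.0  # px
    taper_exponent: float = 3.0
    branch_angle_mean: float = 63.6  # degrees
    branch_angle_sd: float = 7.5  # degrees
    tortuosity_amplitude: float = 5.0  # px, peak lateral offset
    tortuosity_wavelength: float = 130.0  # px
    depth: int = 6  # maximum segment generations
    branch_prob: float = 0.7  # bifurcation probability per tip from generation 2 on;
    # tips otherwise terminate, staggering tree extent independently of caliber
    radial_bias: float = 0.35  # pull of daughter directions toward the radial
    # direction from the disc (keeps each arcade in its own sector, as in real
    # fundi, and limits crossings between neighboring trees)
    seed: int = 0
    split_ratio: float = 0.6  # thin/thick daughter diameter ratio
    root_length: float = 85.0  # px, trunk chord length
    length_ratio: float = 0.92  # per-generation chord shrink
    segment_taper: float = 0.88  # end/start diameter ratio within one segment
    min_caliber: float = 1.8  # px; tips stop branching before daughters go sub-pixel
    straight_margin: float = 16.0  # px of exactly straight path at each segment end

    def __post_init__(self) -> None:
        if not (self.trunk_caliber_vein >= self.trunk_caliber_artery > 0):
            raise ValueError("require trunk_caliber_vein >= trunk_caliber_artery > 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0.0 < self.branch_angle_mean < 180.0):
            raise ValueError("branch_angle_mean must lie in (0, 180) degrees")
        if self.tortuosity_wavelength <= 0:
            raise ValueError("tortuosity_wavelength must be positive")
        if not (0.0 < self.split_ratio <= 1.0):
            raise ValueError("split_ratio must lie in (0, 1]")
        if not (0.0 < self.segment_taper <= 1.0):
            raise ValueError("segment_taper must lie in (0, 1]")


@dataclass(frozen=True)
class DiscSpec:
    """Optic disc / cup geometry and image calibration."""

    center: tuple[float, float] = (622.0, 512.0)  # (x, y) px
    disc_radius: float = 87.0  # px
    cup_radius: float = 42.0  # px
    pixel_pitch: float = 10.0  # µm/px

    def __post_init__(self) -> None:
        if not (0 < self.cup_radius < self.disc_radius):
            raise ValueError("require 0 < cup_radius < disc_radius")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")


def disc_to_ellipse(disc: DiscSpec) -> Ellipse:
    return circle(disc.center, disc.disc_radius)


@dataclass
class GroundTruth:
    vessel_mask: np.ndarray
    artery_mask: np.ndarray
    vein_mask: np.ndarray
    disc: DiscSpec
    graph: VesselGraph
    per_segment_truth: pd.DataFrame  # segment_id, caliber_px, tortuosity, label
    per_branch_truth: pd.DataFrame  # branch_id, angle_deg, x, y

    def validate(self) -> None:
        if (self.artery_mask & self.vein_mask).any():
            raise ValueError("artery and vein truth masks overlap")
        if ((self.artery_mask | self.vein_mask) != self.vessel_mask).any():
            raise ValueError("artery | vein != vessel mask")
        seg_ids = {s.id for s in self.graph.segments}
        if not set(self.per_segment_truth["segment_id"]).issubset(seg_ids):
            raise ValueError("truth table references unknown segment id")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort design (groups "HLC" and "LLC").

    ``group_effects`` are additive offsets applied to the HLC group's true
    parameters; ``covariate_dists`` hold per-group age / sex / axial-length
    distributions.  Subject- and eye-level noise standard deviations control
    how much of each parameter's variance is shared between a subject's two
    eyes.  All values at the truth level (µm, degrees, mm²).
    """

    n_per_group: int = 100
    eyes_per_subject: int = 2
    seed: int = 0
    group_effects: dict = field(
        default_factory=lambda: {
            "caliber_um": -4.0,
            "branch_angle_deg": -1.45,
            "disc_area_mm2": 0.184,
            "cup_area_mm2": 0.068,
        }
    )
    covariate_dists: dict = field(
        default_factory=lambda: {
            "HLC": {
                "age_mean": 8.66,
                "age_sd": 0.66,
                "male_prop": 0.438,
                "axl_mean": 22.76,
                "axl_sd": 1.51,
            },
            "LLC": {
                "age_mean": 8.08,
                "age_sd": 0.28,
                "male_prop": 0.522,
                "axl_mean": 23.27,
                "axl_sd": 0.79,
            },
        }
    )
    # truth-level baselines (LLC group) and noise components
    vc_base_um: float = 82.0
    vc_subject_sd_um: float = 3.0
    vc_eye_sd_um: float = 9.5
    vc_axl_slope_um_per_mm: float = -2.0
    vba_base_deg: float = 63.6
    vba_subject_sd_deg: float = 3.0
    vba_eye_sd_deg: float = 6.9
    disc_area_base_mm2: float = 2.365
    disc_area_subject_sd_mm2: float = 0.35
    disc_area_eye_sd_mm2: float = 0.19
    cup_area_base_mm2: float = 0.557
    cup_area_subject_sd_mm2: float = 0.20
    cup_area_eye_sd_mm2: float = 0.10

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.eyes_per_subject not in (1, 2):
            raise ValueError("eyes_per_subject must be 1 or 2")
        for grp, d in self.covariate_dists.items():
            if not (0.0 <= d["male_prop"] <= 1.0):
                raise ValueError(f"male proportion out of [0, 1] for group {grp}")


# --------------------------------------------------------- tree generation


_MIN_MEANDER_SPAN = 10.0  # px


def _raised_cosine_path(
    p0: np.ndarray,
    direction: np.ndarray,
    length: float,
    amplitude: float,
    n_waves: int,
    side: float,
    straight_margin: float = 16.0,
) -> tuple[np.ndarray, float]:
    """Centerline samples and true tortuosity of one segment.

    The path is chord + lateral squared-raised-cosine offset
    ``side * a * ((1 - cos(2*pi*m*(s-s0)/Li)) / 2)**2`` over the inner span
    ``s in [s0, L - s0]`` (s0 = ``straight_margin``, Li = L - 2*s0), exactly
    straight outside it, sampled at ~1 px arc steps.  The offset, its
    slope, and its curvature all vanish at the inner-span ends, so the path
    is C2, chord length equals ``length`` exactly, and the path leaves each
    segment end along the chord direction — bifurcation angles are
    therefore exactly the angles between daughter chords, and line fits
    near a node see a straight vessel.  Returns (points (N,2),
    arc/chord - 1) with the latter computed by quadrature of the exact
    arc-length integrand.
    """
    n = max(int(math.ceil(length)), 2)
    s = np.linspace(0.0, length, n + 1)
    s0 = straight_margin
    inner = length - 2.0 * s0
    # meanders shorter than this stay straight: their arc excess would sit
    # below the raster resolution of any centerline-based tortuosity measure
    if amplitude == 0.0 or n_waves == 0 or inner < _MIN_MEANDER_SPAN:
        pts = p0[None, :] + s[:, None] * direction[None, :]
        return pts, 0.0
    a = amplitude
    m = n_waves
    u = 2.0 * np.pi * m * np.clip(s - s0, 0.0, inner) / inner
    off = side * a * ((1.0 - np.cos(u)) / 2.0) ** 2
    normal = np.array([-direction[1], direction[0]])
    pts = p0[None, :] + s[:, None] * direction[None, :] + off[:, None] * normal[None, :]
    w = 2.0 * math.pi * m / inner

    def integrand(t: float) -> float:
        ut = w * t
        slope = a * w * (1.0 - math.cos(ut)) * math.sin(ut) / 2.0
        return math.sqrt(1.0 + slope * slope)

    arc_inner, _ = quad(integrand, 0.0, inner, limit=200)
    arc = arc_inner + 2.0 * s0
    return pts, arc / length - 1.0


def _rot(v: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate v by angle_deg; positive angles turn toward -y (up on screen)."""
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([c * v[0] + s * v[1], -s * v[0] + c * v[1]])


def generate_tree(
    spec: TreeSpec,
    disc: DiscSpec,
    kind: str = "artery",
    root_angle_deg: float = 135.0,
    frame_shape: tuple[int, int] = (1024, 1024),
    rng: np.random.Generator | None = None,
) -> VesselGraph:
    """Grow one recursive bifurcating tree rooted at the disc border.

    ``root_angle_deg`` is the direction of the trunk from the disc center in
    the package's screen-angle convention (0 = +x, 90 = up).  Segments whose
    centerline leaves the fundus aperture (inscribed circle) or the frame
    are truncated there, flagged ``excluded``, and left out of the truth
    tables; growth stops at truncation.

    Returns a :class:`VesselGraph` whose ``segment_truth`` /``branch_truth``
    dictionaries hold the exact caliber, arc/chord tortuosity, and
    bifurcation angles used to build the geometry.
    """
    if kind not in ("artery", "vein"):
        raise ValueError("kind must be 'artery' or 'vein'")
    cx, cy = disc.center
    h, w = frame_shape
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("disc center outside the image frame")
    rng = rng or np.random.default_rng(spec.seed)

    g = VesselGraph()
    trunk_w = spec.trunk_caliber_artery if kind == "artery" else spec.trunk_caliber_vein
    direction0 = _rot(np.array([1.0, 0.0]), root_angle_deg)
    p_root = np.array([cx, cy]) + disc.disc_radius * direction0

    ap_c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    ap_r = min(h, w) / 2.0 - 3.0

    g.nodes.append(Node(0, (float(p_root[0]), float(p_root[1])), 0, "endpoint"))

    def in_bounds(pts: np.ndarray, radius: float) -> np.ndarray:
        ok_frame = (
            (pts[:, 0] >= radius)
            & (pts[:, 0] <= w - 1 - radius)
            & (pts[:, 1] >= radius)
            & (pts[:, 1] <= h - 1 - radius)
        )
        ok_ap = np.linalg.norm(pts - ap_c[None, :], axis=1) <= ap_r - radius
        return ok_frame & ok_ap

    def grow(p0: np.ndarray, direction: np.ndarray, caliber: float, gen: int, remaining: int, start_node: int):
        length = spec.root_length * spec.length_ratio**gen * rng.uniform(0.85, 1.15)
        m = max(1, int(round(length / spec.tortuosity_wavelength)))
        side = float(rng.choice([-1.0, 1.0]))
        # the straight end margin grows with caliber: junction blobs scale with
        # the vessel radius, and angle fits must see straight daughters
        margin = max(spec.straight_margin, caliber / 2.0 + 15.0)
        pts, tort = _raised_cosine_path(
            p0, direction, length, spec.tortuosity_amplitude, m, side, margin
        )
        end_caliber = caliber * spec.segment_taper
        radii_full = np.linspace(caliber / 2.0, end_caliber / 2.0, len(pts))
        ok = in_bounds(pts, caliber / 2.0)
        excluded = not bool(ok.all())
        if excluded:
            cut = int(np.argmin(ok))  # first out-of-bounds sample
            if cut < 2:
                return  # segment entirely outside: drop it
            pts = pts[:cut]
        end = pts[-1]
        end_node = len(g.nodes)
        g.nodes.append(Node(end_node, (float(end[0]), float(end[1])), 0, "endpoint"))
        seg_id = len(g.segments)
        radii = radii_full[: len(pts)]
        g.segments.append(Segment(seg_id, pts, radii, kind, (start_node, end_node), excluded))
        if not excluded:
            g.segment_truth[seg_id] = {
                "caliber_px": (caliber + end_caliber) / 2.0,  # mean over the linear taper
                "tortuosity": tort,
                "label": kind,
            }
        if excluded or remaining <= 0:
            return
        if gen >= 2 and rng.random() >= spec.branch_prob:
            return  # tip terminates; caliber-independent, so distal zones keep
            # the same caliber mix as proximal ones (only thinner by taper)
        # Murray split of the parent's end caliber:
        # w1 (thick) and w2 = rho * w1 with w1^e + w2^e = end_caliber^e
        e = spec.taper_exponent
        rho = spec.split_ratio
        w1 = end_caliber / (1.0 + rho**e) ** (1.0 / e)
        w2 = rho * w1
        if w2 * spec.segment_taper < spec.min_caliber:
            return  # thin daughter would drop below raster resolution
        theta = float(rng.normal(spec.branch_angle_mean, spec.branch_angle_sd))
        theta = min(max(theta, 5.0), 175.0)
        # the thicker daughter deviates less from the parent axis
        f_thin = w1**2 / (w1**2 + w2**2)
        side_b = float(rng.choice([-1.0, 1.0]))
        d1 = _rot(direction, -side_b * theta * (1.0 - f_thin))
        d2 = _rot(direction, side_b * theta * f_thin)
        if spec.radial_bias > 0.0:
            radial = end - np.array([cx, cy])
            nrm = np.linalg.norm(radial)
            if nrm > 1e-9:
                radial /= nrm
                d1 = d1 + spec.radial_bias * radial
                d1 /= np.linalg.norm(d1)
                d2 = d2 + spec.radial_bias * radial
                d2 /= np.linalg.norm(d2)
        # the recorded truth is the realized angle between the daughter chords
        true_angle = math.degrees(
            math.acos(float(np.clip(np.dot(d1, d2), -1.0, 1.0)))
        )
        g.branch_truth[end_node] = {
            "angle_deg": true_angle,
            "x": float(end[0]),
            "y": float(end[1]),
        }
        grow(end, d1, w1, gen + 1, remaining - 1, end_node)
        grow(end, d2, w2, gen + 1, remaining - 1, end_node)

    grow(p_root, direction0, trunk_w, 0, spec.depth - 1, 0)

    deg = {n.id: 0 for n in g.nodes}
    for s in g.segments:
        deg[s.nodes[0]] += 1
        deg[s.nodes[1]] += 1
    for n in g.nodes:
        n.degree = deg[n.id]
        n.kind = "bifurcation" if n.degree >= 3 else "endpoint"
    # bifurcations that lost daughters to truncation are not true branch points
    for nid in list(g.branch_truth):
        if g.node_by_id(nid).degree < 3:
            del g.branch_truth[nid]
    return g


# --------------------------------------------------------------- rendering


def _stamp_polyline(out: np.ndarray, points: np.ndarray, radii: np.ndarray) -> None:
    """Mark every pixel whose center lies within the local radius of the polyline.

    Radius varies linearly along each edge.  Exact for constant radius: the
    union over edges of {dist(p, edge) <= r} equals {dist(p, polyline) <= r}.
    """
    h, w = out.shape
    if len(points) == 1:
        x, y = points[0]
        r = float(radii[0])
        _stamp_disk(out, x, y, r)
        return
    for i in range(len(points) - 1):
        p0, p1 = points[i], points[i + 1]
        r0, r1 = float(radii[i]), float(radii[i + 1])
        rmax = max(r0, r1)
        x0 = int(max(0, math.floor(min(p0[0], p1[0]) - rmax - 1)))
        x1 = int(min(w - 1, math.ceil(max(p0[0], p1[0]) + rmax + 1)))
        y0 = int(max(0, math.floor(min(p0[1], p1[1]) - rmax - 1)))
        y1 = int(min(h - 1, math.ceil(max(p0[1], p1[1]) + rmax + 1)))
        if x0 > x1 or y0 > y1:
            continue
        yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
        dx, dy = p1[0] - p0[0], p1[1] - p0[1]
        denom = dx * dx + dy * dy
        if denom == 0:
            _stamp_disk(out, p0[0], p0[1], rmax)
            continue
        t = ((xx - p0[0]) * dx + (yy - p0[1]) * dy) / denom
        t = np.clip(t, 0.0, 1.0)
        px = p0[0] + t * dx
        py = p0[1] + t * dy
        rr = r0 + t * (r1 - r0)
        hit = (xx - px) ** 2 + (yy - py) ** 2 <= rr * rr
        out[y0 : y1 + 1, x0 : x1 + 1] |= hit


def _stamp_disk(out: np.ndarray, x: float, y: float, r: float) -> None:
    h, w = out.shape
    x0 = int(max(0, math.floor(x - r - 1)))
    x1 = int(min(w - 1, math.ceil(x + r + 1)))
    y0 = int(max(0, math.floor(y - r - 1)))
    y1 = int(min(h - 1, math.ceil(y + r + 1)))
    if x0 > x1 or y0 > y1:
        return
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    out[y0 : y1 + 1, x0 : x1 + 1] |= (xx - x) ** 2 + (yy - y) ** 2 <= r * r


def _merge_graphs(trees: list[VesselGraph]) -> VesselGraph:
    merged = VesselGraph()
    for g in trees:
        n_off = len(merged.nodes)
        s_off = len(merged.segments)
        for n in g.nodes:
            merged.nodes.append(Node(n.id + n_off, n.position, n.degree, n.kind))
        for s in g.segments:
            merged.segments.append(
                Segment(
                    s.id + s_off,
                    s.points.copy(),
                    s.radii.copy(),
                    s.label,
                    (s.nodes[0] + n_off, s.nodes[1] + n_off),
                    s.excluded,
                )
            )
        for sid, rec in g.segment_truth.items():
            merged.segment_truth[sid + s_off] = dict(rec)
        for nid, rec in g.branch_truth.items():
            merged.branch_truth[nid + n_off] = dict(rec)
    return merged


def render_fundus(
    trees: list[VesselGraph],
    disc: DiscSpec,
    noise_level: float = 0.02,
    seed: int = 0,
    frame_shape: tuple[int, int] = (1024, 1024),
    eye: str = "OD",
    subject_id: str = "synthetic",
) -> tuple[FundusImage, GroundTruth]:
    """Rasterize trees + disc into an RGB fundus-like photograph with truth.

    Vessels are stamped as disks of the local radius along each centerline
    (veins darker and wider than arteries by construction of the specs); the
    disc is a bright ellipse with a brighter concentric cup; the background
    carries a smooth vignette and illumination gradient plus Gaussian pixel
    noise of ``noise_level`` (fraction of dynamic range).  The ground-truth
    masks equal the union of stamped disks exactly and are independent of
    the noise seed.
    """
    if not trees:
        raise ValueError("trees must be non-empty")
    h, w = frame_shape
    artery_r = np.zeros(frame_shape, dtype=bool)
    vein_r = np.zeros(frame_shape, dtype=bool)
    for g in trees:
        for s in g.segments:
            if np.any(np.asarray(s.radii) <= 0):
                raise ValueError(f"zero-radius segment (id {s.id}) cannot be rendered")
            target = artery_r if s.label == "artery" else vein_r
            _stamp_polyline(target, np.asarray(s.points, dtype=float), np.asarray(s.radii, dtype=float))
    # overlap (artery-vein crossing) resolves to the vein, which lies on top
    artery_m = artery_r & ~vein_r
    vein_m = vein_r
    vessel_m = artery_m | vein_m

    yy, xx = np.mgrid[0:h, 0:w]
    ap_c = ((w - 1) / 2.0, (h - 1) / 2.0)
    ap_r = min(h, w) / 2.0 - 2.0
    dist_ap = np.sqrt((xx - ap_c[0]) ** 2 + (yy - ap_c[1]) ** 2)
    roi = dist_ap <= ap_r

    g_chan = 0.42 - 0.10 * (dist_ap / ap_r) ** 2 + 0.03 * (xx / w - 0.5)
    cx, cy = disc.center
    dist_disc = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    g_chan[dist_disc <= disc.disc_radius] = 0.72
    g_chan[dist_disc <= disc.cup_radius] = 0.88
    g_chan[artery_m] -= 0.18
    g_chan[vein_m] -= 0.26

    rng = np.random.default_rng(seed)
    if noise_level > 0:
        g_chan = g_chan + rng.normal(0.0, noise_level, size=frame_shape)
    g_chan = np.clip(g_chan, 0.0, 1.0)

    r_chan = np.clip(g_chan * 0.85 + 0.25, 0.0, 1.0)
    b_chan = np.clip(g_chan * 0.40, 0.0, 1.0)
    rgb = np.stack([r_chan, g_chan, b_chan], axis=2)
    rgb[~roi] = 0.0
    pixels = np.round(rgb * 255.0).astype(np.uint8)

    merged = _merge_graphs(trees)
    seg_rows = [
        {"segment_id": sid, **rec} for sid, rec in sorted(merged.segment_truth.items())
    ]
    br_rows = [{"branch_id": nid, **rec} for nid, rec in sorted(merged.branch_truth.items())]
    truth = GroundTruth(
        vessel_mask=vessel_m,
        artery_mask=artery_m,
        vein_mask=vein_m,
        disc=disc,
        graph=merged,
        per_segment_truth=pd.DataFrame(
            seg_rows, columns=["segment_id", "caliber_px", "tortuosity", "label"]
        ),
        per_branch_truth=pd.DataFrame(br_rows, columns=["branch_id", "angle_deg", "x", "y"]),
    )
    image = FundusImage(
        pixels=pixels, pixel_pitch=disc.pixel_pitch, eye=eye, subject_id=subject_id
    )
    return image, truth


# --------------------------------------------------------------- scenes


_ARCADE_AXES_OD = (130.0, 230.0, 50.0, 310.0)  # ST, IT, SN, IN screen angles for OD
_AV_OFFSET_DEG = 14.0
_NASAL_TRUNK_SCALE = 0.85


def build_scene(
    tree_spec: TreeSpec,
    disc: DiscSpec,
    eye: str = "OD",
    frame_shape: tuple[int, int] = (1024, 1024),
    noise_level: float = 0.02,
    seed: int = 0,
    subject_id: str = "synthetic",
) -> tuple[FundusImage, GroundTruth]:
    """Render a full eight-tree scene (artery + vein along four arcades).

    Arteries and veins run paired along the superotemporal, inferotemporal,
    superonasal and inferonasal arcades, angularly offset so the paired
    trees rarely cross near the disc; nasal trunks are slightly thinner, as
    in real fundus anatomy.
    """
    trees = []
    axes = _ARCADE_AXES_OD if eye == "OD" else tuple((180.0 - a) % 360.0 for a in _ARCADE_AXES_OD)
    rng = np.random.default_rng(seed)
    for i, axis in enumerate(axes):
        nasal = i >= 2
        scale = _NASAL_TRUNK_SCALE if nasal else 1.0
        sub = TreeSpec(
            **{
                **asdict(tree_spec),
                "trunk_caliber_artery": tree_spec.trunk_caliber_artery * scale,
                "trunk_caliber_vein": tree_spec.trunk_caliber_vein * scale,
                "depth": tree_spec.depth if not nasal else max(tree_spec.depth - 1, 1),
            }
        )
        for kind, off in (("artery", _AV_OFFSET_DEG), ("vein", -_AV_OFFSET_DEG)):
            tree_rng = np.random.default_rng(int(rng.integers(2**31)))
            trees.append(
                generate_tree(
                    sub,
                    disc,
                    kind=kind,
                    root_angle_deg=(axis + off) % 360.0,
                    frame_shape=frame_shape,
                    rng=tree_rng,
                )
            )
    return render_fundus(
        trees,
        disc,
        noise_level=noise_level,
        seed=int(rng.integers(2**31)),
        frame_shape=frame_shape,
        eye=eye,
        subject_id=subject_id,
    )


def default_scene(seed: int = 0, frame_shape: tuple[int, int] = (1024, 1024)):
    """The default synthetic scene: default tree and disc specs, default noise."""
    h, w = frame_shape
    disc = DiscSpec(center=(w / 2.0 + 0.107 * w, h / 2.0))
    return build_scene(TreeSpec(seed=seed), disc, eye="OD", frame_shape=frame_shape, seed=seed)


# ----------------------------------------------------------------- cohorts


def draw_cohort_parameters(spec: CohortSpec) -> pd.DataFrame:
    """Draw per-eye true parameters and covariates for the two-group design.

    Returns one row per eye with columns: subject_id, eye, group, age, sex,
    axl_mm, vc_true_um, vba_true_deg, disc_area_true_mm2, cup_area_true_mm2.
    Both eyes of a subject share the covariates and the subject-level
    component of each parameter; fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    eyes = ["OD", "OS"][: spec.eyes_per_subject]
    axl_ref = 23.0  # grand reference for the caliber-vs-axial-length slope
    rows = []
    for group in ("HLC", "LLC"):
        cov = spec.covariate_dists[group]
        eff = spec.group_effects if group == "HLC" else {}
        for i in range(spec.n_per_group):
            sid = f"{group}-{i:04d}"
            age = float(rng.normal(cov["age_mean"], cov["age_sd"]))
            sex = "male" if rng.random() < cov["male_prop"] else "female"
            axl = float(rng.normal(cov["axl_mean"], cov["axl_sd"]))
            subj = {
                "vc": float(rng.normal(0.0, spec.vc_subject_sd_um)),
                "vba": float(rng.normal(0.0, spec.vba_subject_sd_deg)),
                "disc": float(rng.normal(0.0, spec.disc_area_subject_sd_mm2)),
                "cup": float(rng.normal(0.0, spec.cup_area_subject_sd_mm2)),
            }
            for eye in eyes:
                vc = (
                    spec.vc_base_um
                    + eff.get("caliber_um", 0.0)
                    + spec.vc_axl_slope_um_per_mm * (axl - axl_ref)
                    + subj["vc"]
                    + float(rng.normal(0.0, spec.vc_eye_sd_um))
                )
                vba = (
                    spec.vba_base_deg
                    + eff.get("branch_angle_deg", 0.0)
                    + subj["vba"]
                    + float(rng.normal(0.0, spec.vba_eye_sd_deg))
                )
                disc_a = (
                    spec.disc_area_base_mm2
                    + eff.get("disc_area_mm2", 0.0)
                    + subj["disc"]
                    + float(rng.normal(0.0, spec.disc_area_eye_sd_mm2))
                )
                cup_a = (
                    spec.cup_area_base_mm2
                    + eff.get("cup_area_mm2", 0.0)
                    + subj["cup"]
                    + float(rng.normal(0.0, spec.cup_area_eye_sd_mm2))
                )
                disc_a = max(disc_a, 1.0)
                cup_a = float(np.clip(cup_a, 0.08 * disc_a, 0.55 * disc_a))
                rows.append(
                    {
                        "subject_id": sid,
                        "eye": eye,
                        "group": group,
                        "age": age,
                        "sex": sex,
                        "axl_mm": axl,
                        "vc_true_um": max(vc, 40.0),
                        "vba_true_deg": float(np.clip(vba, 20.0, 160.0)),
                        "disc_area_true_mm2": disc_a,
                        "cup_area_true_mm2": cup_a,
                    }
                )
    return pd.DataFrame(rows)


def eye_scene_specs(
    row: pd.Series | dict,
    frame_shape: tuple[int, int] = (1024, 1024),
    pixel_pitch: float = 10.0,
    tree_defaults: TreeSpec | None = None,
) -> tuple[TreeSpec, DiscSpec]:
    """Map one cohort row's true parameters to a TreeSpec / DiscSpec pair.

    The trunk caliber is set so that the tree-wide caliber tracks the drawn
    true value (trunks run ~1.25x the tree's mean width); the disc and cup
    radii come from the drawn areas via the equal-area circle.
    """
    td = tree_defaults or TreeSpec()
    h, w = frame_shape
    trunk_artery = row["vc_true_um"] / pixel_pitch * 1.25
    disc_r_px = math.sqrt(row["disc_area_true_mm2"] / math.pi) * 1000.0 / pixel_pitch
    cup_r_px = math.sqrt(row["cup_area_true_mm2"] / math.pi) * 1000.0 / pixel_pitch
    nasal_sign = 1.0 if row["eye"] == "OD" else -1.0
    disc = DiscSpec(
        center=(w / 2.0 + nasal_sign * 0.107 * w, h / 2.0),
        disc_radius=disc_r_px,
        cup_radius=min(cup_r_px, 0.9 * disc_r_px),
        pixel_pitch=pixel_pitch,
    )
    tree = TreeSpec(
        **{
            **asdict(td),
            "trunk_caliber_artery": trunk_artery,
            "trunk_caliber_vein": trunk_artery * 1.25,
            "branch_angle_mean": float(row["vba_true_deg"]),
        }
    )
    return tree, disc


def generate_cohort(
    spec: CohortSpec,
    render: bool = True,
    frame_shape: tuple[int, int] = (1024, 1024),
    pixel_pitch: float = 10.0,
    noise_level: float = 0.02,
    tree_defaults: TreeSpec | None = None,
) -> tuple[list[FundusImage], list[GroundTruth], pd.DataFrame]:
    """Generate the full two-cohort study: images, truths, covariate table.

    With ``render=False`` only the covariate/true-parameter table is
    produced (images and truths empty) — the fast path for statistical
    power studies that operate on the truth level.
    """
    params = draw_cohort_parameters(spec)
    images: list[FundusImage] = []
    truths: list[GroundTruth] = []
    if render:
        seed_rng = np.random.default_rng(spec.seed + 1)
        for _, row in params.iterrows():
            tree, disc = eye_scene_specs(row, frame_shape, pixel_pitch, tree_defaults)
            img, truth = build_scene(
                tree,
                disc,
                eye=row["eye"],
                frame_shape=frame_shape,
                noise_level=noise_level,
                seed=int(seed_rng.integers(2**31)),
                subject_id=row["subject_id"],
            )
            images.append(img)
            truths.append(truth)
    return images, truths, params
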