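"""Synthetic study generator.

Every input the pipeline consumes can be generated here, so the whole
analysis is exercised end to end without external data: parametric mandible
landmark configurations whose MA curves realise prescribed diet-class
profiles, distorted "fossil" fragments for testing the composite
representation, pure-birth (Yule) trees, Brownian-motion trait simulation,
and a full study bundle mirroring the design of the comparative dataset
(43 extant species plus one composite fossil).

Diet-class profiles encode the qualitative contrast the comparative data
show: herbivore-leaning taxa sit high in the MA range with an almost linear
decrease toward the distal incisivi, carnivore-leaning taxa sit low with a
gently exponential decrease, and omnivores lie in between.  Mandibles are
built by inverting the lever formula — edge points are placed at distance
inlever / ma*(s) from the pivot along a smooth fan — so the target profile
is an exact oracle for :func:`gnathomech.mechanics.ma_curve` at zero noise.

All species share a smooth tooth-row relief waveform (an exact fifth-order
polynomial modulation scaling with curve level), so the curves carry
genuine fifth-order structure for the downstream order selection to find.
Phylogenetic structure is injected at the parameter level: Brownian-motion
jitter on (level, curvature, relief amplitudes) across the simulated tree,
so the phylogenetic signal in the downstream polynomial coefficients is
genuine rather than painted onto the curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .landmarks import LandmarkConfiguration
from .phylo import Phylogeny

DIET_CLASSES = ("herbivore", "omnivore", "carnivore")


@dataclass
class DietProfileSpec:
    """Parameters of one diet-class MA profile.

    ``level`` is the vertical position of the curve (MA at s = 0 up to the
    floor term); ``shape`` selects an almost linear or gently exponential
    decrease with ``curvature`` controlling its strength; ``floor`` is the
    asymptotic offset of the exponential profile; ``noise_sd`` is isotropic
    landmark noise applied when a mandible is generated from the profile.
    """

    diet_class: str
    level: float
    shape: str
    curvature: float
    noise_sd: float = 0.0
    floor: float = 0.1
    #: tooth-row relief: amplitudes of shifted Legendre polynomials P3, P4,
    #: P5... multiplying the base profile by 1 + sum a_k P~_k(s).  The relief
    #: waveform is an exact low-order polynomial, mirroring the smooth
    #: molar-to-incisivi relief of the gnathal edge.
    relief: tuple = ()

    def __post_init__(self):
        if self.diet_class not in DIET_CLASSES:
            raise ValueError(f"unknown diet class {self.diet_class!r}")
        if self.shape not in ("linear", "exponential"):
            raise ValueError(f"unknown profile shape {self.shape!r}")
        if self.level <= 0:
            raise ValueError("level must be positive")
        if self.curvature < 0 or self.noise_sd < 0 or self.floor < 0:
            raise ValueError("curvature, noise_sd and floor must be non-negative")
        if sum(abs(a) for a in self.relief) >= 1.0:
            raise ValueError("total relief amplitude must stay below 1")
        # positivity of ma(s) on [0, 1]
        profile = target_ma_profile(self)
        if np.min(profile(np.linspace(0.0, 1.0, 201))) <= 1e-12:
            raise ValueError(
                "profile parameters give non-positive MA on [0, 1]")


def target_ma_profile(spec: DietProfileSpec):
    """Return the target MA profile s -> ma for a diet-class spec.

    linear: ma(s) = level (1 - curvature s);
    exponential: ma(s) = level exp(-curvature s) + floor.

    Either base gains an additive relief term ``level * sum a_k P~_k(s)``
    over the spec's relief amplitudes (shifted Legendre polynomials
    starting at degree 3): a smooth, exactly low-order modulation of the
    tooth row whose absolute amplitude scales with the curve's level, as
    tooth relief scales with overall mandible mechanics.
    """
    from scipy.special import eval_sh_legendre

    level, curv, floor = spec.level, spec.curvature, spec.floor
    shape, relief = spec.shape, tuple(spec.relief)

    def profile(s):
        s = np.asarray(s, float)
        if shape == "linear":
            base = level * (1.0 - curv * s)
        else:
            base = level * np.exp(-curv * s) + floor
        for k, a in enumerate(relief, start=3):
            base = base + level * a * eval_sh_legendre(k, s)
        return base

    return profile


#: Tooth-row relief waveform shared across the clade (P3, P4, P5
#: amplitudes); species deviate from it by small heritable amounts.
BASE_RELIEF = (0.06, 0.05, 0.04)

#: Default class profiles: herbivores high with an almost linear decrease
#: (gentle exponential, curvature 0.35), carnivores low with a marked
#: exponential decrease, omnivores intermediate in both level and
#: curvature.  Keeping all three classes on one curve family makes the
#: omnivore profile geometrically intermediate between the other two in
#: coefficient space, as the intermediate diet should be.
DIET_DEFAULTS: dict[str, DietProfileSpec] = {
    "herbivore": DietProfileSpec("herbivore", level=0.6, shape="exponential",
                                 curvature=0.35, relief=BASE_RELIEF),
    "omnivore": DietProfileSpec("omnivore", level=0.45, shape="exponential",
                                curvature=0.8, relief=BASE_RELIEF),
    "carnivore": DietProfileSpec("carnivore", level=0.3, shape="exponential",
                                 curvature=1.5, relief=BASE_RELIEF),
}


def mandible_from_profile(spec: DietProfileSpec, n_edge_points: int = 1600,
                          seed: int | None = None,
                          specimen_id: str = "synthetic",
                          fan_start: float = -0.25, fan_angle: float = 1.0,
                          ) -> LandmarkConfiguration:
    """Build a 2D mandible whose MA curve realises the target profile.

    The pivot sits at the origin with the adductor attachment at unit
    distance, so MA at an edge point equals 1 / (distance to pivot).  Edge
    vertex i sits at exactly the uniform arc-length fraction
    s_i = i / (n - 1) of the polyline with radius 1 / ma*(s_i): the radii
    are fixed by the profile and the fan of directions is solved for the
    common chord length that spans ``fan_angle`` (bisection on the
    law-of-cosines angle increments).  :func:`gnathomech.mechanics.ma_curve`
    therefore recovers ma* exactly at the vertices when ``noise_sd`` is
    zero, with only O(1/n^2) chord-interpolation error in between.
    Gaussian noise of sd ``spec.noise_sd`` is then added to each edge
    landmark along the local edge normal; the joint pivot and the adductor
    attachment stay exact.  This emulates digitization of a continuous
    contour: the condyle and apodeme attachment are sharply defined points,
    while tracing the worn, toothed gnathal edge errs across the drawn line
    (displacement along the contour is not an error at all).  Normal-only
    noise perturbs arc length just at second order, so the resulting MA
    curves carry approximately white measurement noise rather than a smooth
    warp of the position axis.
    """
    if n_edge_points < 4:
        raise ValueError("n_edge_points must be >= 4")
    profile = target_ma_profile(spec)
    s = np.linspace(0.0, 1.0, n_edge_points)
    r = 1.0 / profile(s)
    rr = r[:-1] * r[1:]
    sq = r[:-1] ** 2 + r[1:] ** 2

    def angle_span(chord: float) -> np.ndarray:
        return np.arccos(np.clip((sq - chord * chord) / (2.0 * rr), -1.0, 1.0))

    # Feasibility: each chord must exceed its radius change, so steep
    # profiles impose a minimum total angle; widen the fan when needed.
    lo = float(np.max(np.abs(np.diff(r)))) * (1.0 + 1e-12)
    if lo > 0:
        fan_angle = max(fan_angle, float(angle_span(lo).sum()) * (1.0 + 1e-9))
    hi = max(2.0 * lo, float(r.max()) * fan_angle, 1e-6)
    while angle_span(hi).sum() < fan_angle:
        hi *= 2.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if angle_span(mid).sum() < fan_angle:
            lo = mid
        else:
            hi = mid
    theta = fan_start + np.concatenate([[0.0], np.cumsum(angle_span(hi))])
    edge = r[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
    inlever_dir = fan_start - 1.8
    inlever = np.array([np.cos(inlever_dir), np.sin(inlever_dir)])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        tangent = np.gradient(edge, axis=0)
        tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
        normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
        edge = edge + normal * rng.normal(0.0, spec.noise_sd,
                                          size=n_edge_points)[:, None]
    coords = np.vstack([[0.0, 0.0], inlever, edge])
    labels = ["joint", "adductor"] + [f"edge_{i:03d}" for i in range(n_edge_points)]
    roles = {"joint": "condyle_anterior", "adductor": "adductor_attachment"}
    roles.update({lab: "edge_point" for lab in labels[2:]})
    return LandmarkConfiguration(specimen_id, labels, coords, side="left",
                                 role_labels=roles)


def fragment_fossil(config: LandmarkConfiguration, n_copies: int = 4,
                    distortion_sd: float = 0.02, seed: int | None = None,
                    reflect_probability: float = 0.0,
                    ) -> list[LandmarkConfiguration]:
    """Simulate distorted fossil replicates of one mandible.

    Each copy receives a random rigid motion (rotation + translation), an
    optional reflection (negated first axis, side relabelled), and isotropic
    landmark noise of sd ``distortion_sd`` — emulating independently
    preserved, individually distorted fossil specimens of one species.
    """
    if n_copies < 2:
        raise ValueError("n_copies must be >= 2")
    rng = np.random.default_rng(seed)
    d = config.ndim
    copies = []
    for i in range(n_copies):
        coords = config.coords.copy()
        side = config.side
        if rng.random() < reflect_probability:
            coords[:, 0] = -coords[:, 0]
            if side in ("left", "right"):
                side = "right" if side == "left" else "left"
        if d == 2:
            theta = rng.uniform(0.0, 2.0 * np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
        else:
            from scipy.stats import special_ortho_group
            rot = special_ortho_group.rvs(3, random_state=rng)
        coords = coords @ rot.T + rng.uniform(-10.0, 10.0, size=d)
        if distortion_sd > 0:
            coords = coords + rng.normal(0.0, distortion_sd, size=coords.shape)
        copies.append(config.with_coords(
            coords, specimen_id=f"{config.specimen_id}_frag{i + 1}", side=side))
    return copies


def simulate_tree(n_tips: int, seed: int | None = None,
                  birth_rate: float = 1.0) -> Phylogeny:
    """Simulate a pure-birth (Yule) tree with exponential waiting times.

    Starting from two lineages, at rate ``birth_rate`` per lineage a random
    lineage splits; after the n-th tip appears all pending edges are
    extended by a final exponential waiting time.  Tips are labelled
    ``T1..Tn`` in leaf traversal order.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        root.add_child(child)
        active.append(child)
    while len(active) < n_tips:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.edge.length += wait
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            parent.add_child(child)
            active.append(child)
    final = rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.edge.length += final
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = tree.taxon_namespace.new_taxon(f"T{i}")
    return Phylogeny(tree)


def simulate_bm_traits(tree: Phylogeny, n_traits: int, rate: float = 1.0,
                       seed: int | None = None) -> np.ndarray:
    """Draw tip traits under Brownian motion on the tree (root state 0).

    Each column is an independent draw from N(0, rate * C); rows follow the
    tree's tip order.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    C = tree.covariance()
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance: tree has zero-depth tips") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((tree.n_tips, n_traits))
    return np.sqrt(rate) * (L @ z)


@dataclass
class StudyBundle:
    """A complete synthetic comparative study.

    Fields mirror the pipeline inputs: per-species landmark configurations,
    diet labels, the species tree (with the fossil tip grafted when a fossil
    is included), the distorted fossil fragments, the noise-free fossil
    configuration used to build them, and the per-species profile specs
    actually realised.
    """

    configs: list[LandmarkConfiguration]
    diet: dict[str, str]
    tree: Phylogeny
    fossil_fragments: list[LandmarkConfiguration] = field(default_factory=list)
    fossil_true: LandmarkConfiguration | None = None
    fossil_id: str | None = None
    profiles: dict[str, DietProfileSpec] = field(default_factory=dict)
    seed: int | None = None


def make_study(n_species: int = 43,
               class_mix: dict[str, float] | None = None,
               seed: int | None = None,
               include_fossil: bool = True,
               fossil_id: str = "CFMR",
               n_edge_points: int = 50,
               noise_sd: float = 0.005,
               level_jitter_sd: float = 0.04,
               curvature_jitter_sd: float = 0.12,
               relief_jitter_sd: float = 0.004,
               n_fossil_fragments: int = 4,
               fossil_distortion_sd: float = 0.02,
               profiles: dict[str, DietProfileSpec] | None = None,
               ) -> StudyBundle:
    """Generate an end-to-end study fixture.

    A Yule tree is simulated and diet classes are assigned to contiguous
    blocks of the leaf order (so classes are clades and phylogenetic signal
    exists by construction).  Each species' (level, curvature) is its class
    default plus Brownian-motion jitter on the tree, and its mandible is
    generated from that profile with landmark noise.  The fossil is built
    from the intermediate (omnivore) class profile, fragmented into
    distorted copies, and its tip is grafted onto the stem edge of the
    omnivore clade.
    """
    if class_mix is None:
        class_mix = {"herbivore": 0.4, "omnivore": 0.3, "carnivore": 0.3}
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    if seed is None:
        raise ValueError("make_study requires a seed")
    profiles_by_class = dict(DIET_DEFAULTS)
    if profiles:
        profiles_by_class.update(profiles)
    ss = np.random.SeedSequence(seed)
    s_tree, s_bm, s_mand, s_frag = (int(s.generate_state(1)[0] % 2**31)
                                    for s in ss.spawn(4))

    tree = simulate_tree(n_species, seed=s_tree)
    labels = list(tree.tip_labels)

    # Assign classes to whole clades: walk the tree from the root, packing
    # each maximal subtree that fits into the class with the largest
    # remaining demand, so every class is a union of a few genuine clades
    # and phylogenetic signal exists by construction.
    counts = {}
    remaining_total = n_species
    classes = [c for c in DIET_CLASSES if c in class_mix]
    for c in classes[:-1]:
        counts[c] = int(round(class_mix[c] * n_species))
        remaining_total -= counts[c]
    counts[classes[-1]] = remaining_total
    node_leaves: dict = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            node_leaves[node] = [node.taxon.label]
        else:
            node_leaves[node] = [lab for ch in node.child_nodes()
                                 for lab in node_leaves[ch]]
    diet: dict[str, str] = {}
    chunks: dict[str, list[list[str]]] = {c: [] for c in classes}
    state = {"i": 0, "left": counts[classes[0]]}

    def _current_class() -> str:
        while state["left"] == 0 and state["i"] < len(classes) - 1:
            state["i"] += 1
            state["left"] = counts[classes[state["i"]]]
        return classes[state["i"]]

    def _pack(node):
        labs = node_leaves[node]
        cls = _current_class()
        if len(labs) <= state["left"]:
            for lab in labs:
                diet[lab] = cls
            chunks[cls].append(labs)
            state["left"] -= len(labs)
        else:
            for child in sorted(node.child_nodes(),
                                key=lambda ch: -len(node_leaves[ch])):
                _pack(child)

    _pack(tree.tree.seed_node)

    # BM jitter on (level, curvature): rates set so tip sd matches the
    # requested jitter at the mean tip depth
    mean_depth = float(np.mean(tree.tip_depths()))
    n_relief = len(profiles_by_class["omnivore"].relief)
    jitter_sds = [level_jitter_sd, curvature_jitter_sd] + \
        [relief_jitter_sd] * n_relief
    jitter = np.column_stack([
        simulate_bm_traits(tree, 1, rate=sd**2 / mean_depth,
                           seed=s_bm + j)[:, 0]
        for j, sd in enumerate(jitter_sds)])

    mand_rng = np.random.default_rng(s_mand)
    configs, realised = [], {}
    for i, lab in enumerate(labels):
        base = profiles_by_class[diet[lab]]
        level = float(np.clip(base.level + jitter[i, 0], 0.1, 1.5))
        curv = float(base.curvature + jitter[i, 1])
        if base.shape == "linear":
            curv = float(np.clip(curv, 0.0, 0.9))
        else:
            curv = float(np.clip(curv, 0.2, 3.0))
        relief = tuple(
            float(np.clip(a + jitter[i, 2 + j], -0.2, 0.2))
            for j, a in enumerate(base.relief))
        spec = replace(base, level=level, curvature=curv, noise_sd=noise_sd,
                       relief=relief)
        realised[lab] = spec
        configs.append(mandible_from_profile(
            spec, n_edge_points=n_edge_points,
            seed=int(mand_rng.integers(2**31)), specimen_id=lab))

    bundle = StudyBundle(configs=configs, diet=diet, tree=tree,
                         profiles=realised, seed=seed)
    if include_fossil:
        fossil_spec = replace(profiles_by_class["omnivore"], noise_sd=0.0)
        fossil_true = mandible_from_profile(
            fossil_spec, n_edge_points=n_edge_points,
            specimen_id=f"{fossil_id}_true")
        fragments = fragment_fossil(
            fossil_true, n_copies=n_fossil_fragments,
            distortion_sd=fossil_distortion_sd, seed=s_frag,
            reflect_probability=0.5)
        omn_chunks = chunks.get("omnivore") or [labels]
        omn = max(omn_chunks, key=len)
        below = omn[0] if len(omn) == 1 else f"{omn[0]}|{omn[-1]}"
        bundle.tree = tree.attach_tip(fossil_id, below=below, stem_fraction=0.5)
        bundle.fossil_fragments = fragments
        bundle.fossil_true = fossil_true
        bundle.fossil_id = fossil_id
        bundle.diet[fossil_id] = "omnivore"
        bundle.profiles[fossil_id] = fossil_spec
    return bundle
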