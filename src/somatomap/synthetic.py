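"""Synthetic cortical-patch cohort generator.

Builds a flat triangulated patch standing in for the postcentral strip,
band-shaped hand/face ROIs with a border anchor, per-subject ground-truth
somatotopic patterns (Gaussian blobs ordered forehead < nose < lips < tongue
along the medial->lateral axis), block-design time series, and a
questionnaire table, so every downstream stage can be tested without any
external data.

All geometry is in millimetres. The patch is flat, so planar distance is an
analytic oracle for the graph-geodesic code downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import sparse

from .exceptions import InvalidGeometryError, InvalidParameterError

FACE_CONDITIONS: Tuple[str, ...] = ("forehead", "nose", "lips", "tongue")
HEMISPHERES: Tuple[str, str] = ("deprived", "intact")
GROUPS: Tuple[str, ...] = ("controls", "amputees", "one_handers")

_ID_PREFIX = {"controls": "CT", "amputees": "AA", "one_handers": "CA"}


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Triangulated 2-manifold patch.

    ``vertices`` is an (n, 3) float array in mm, ``triangles`` an (m, 3)
    integer array of 0-based vertex indices, and ``axis`` the designated
    medial->lateral coordinate of each vertex (mm).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    axis: np.ndarray

    _edges: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    _adjacency: Optional[sparse.csr_matrix] = field(default=None, repr=False, compare=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) array, sorted pairs."""
        if self._edges is None:
            tri = self.triangles
            pairs = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [0, 2]]])
            pairs = np.sort(pairs, axis=1)
            self._edges = np.unique(pairs, axis=0)
        return self._edges

    @property
    def adjacency(self) -> sparse.csr_matrix:
        """Sparse symmetric matrix of Euclidean edge lengths."""
        if self._adjacency is None:
            e = self.edges
            w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
            n = self.n_vertices
            mat = sparse.coo_matrix(
                (np.concatenate([w, w]),
                 (np.concatenate([e[:, 0], e[:, 1]]),
                  np.concatenate([e[:, 1], e[:, 0]]))),
                shape=(n, n),
            )
            self._adjacency = mat.tocsr()
        return self._adjacency

    def triangle_areas(self) -> np.ndarray:
        a = self.vertices[self.triangles[:, 0]]
        b = self.vertices[self.triangles[:, 1]]
        c = self.vertices[self.triangles[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def build_flat_patch_mesh(n_medial: int, n_lateral: int, spacing: float) -> SurfaceMesh:
    """Regular triangulated grid of ``n_medial`` rows x ``n_lateral`` columns.

    Vertex ``i * n_lateral + j`` sits at ``(j * spacing, i * spacing, 0)``;
    the medial->lateral coordinate is the x (column) coordinate. Each grid
    quad is split into two triangles along a consistent diagonal.
    """
    if n_medial < 2 or n_lateral < 2:
        raise InvalidParameterError("grid must be at least 2 x 2")
    if spacing <= 0:
        raise InvalidParameterError("spacing must be positive")

    jj, ii = np.meshgrid(np.arange(n_lateral), np.arange(n_medial))
    x = (jj * spacing).ravel()
    y = (ii * spacing).ravel()
    vertices = np.column_stack([x, y, np.zeros_like(x)]).astype(float)

    tris: List[Tuple[int, int, int]] = []
    for i in range(n_medial - 1):
        for j in range(n_lateral - 1):
            v00 = i * n_lateral + j
            v01 = v00 + 1
            v10 = v00 + n_lateral
            v11 = v10 + 1
            tris.append((v00, v10, v01))
            tris.append((v10, v11, v01))
    return SurfaceMesh(vertices=vertices, triangles=np.asarray(tris, dtype=int), axis=x.copy())


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

@dataclass
class RoiSet:
    """Vertex-index sets for the analysis ROIs plus the border anchor."""

    hand: np.ndarray
    face: np.ndarray
    s1_combined: np.ndarray
    hand_trimmed: np.ndarray
    face_trimmed: np.ndarray
    anchor_path: np.ndarray     # ordered along the hand ROI's lateral border
    anchor_midpoint: int


def define_rois(mesh: SurfaceMesh, hand_extent: float, face_extent: float,
                rsa_gap: float) -> RoiSet:
    """Band-shaped hand (medial) and face (lateral) ROIs on the patch.

    The hand ROI collects vertices with medial->lateral coordinate strictly
    below ``hand_extent``; the face ROI collects those within ``face_extent``
    of the lateral edge. RSA ROIs are trimmed by ``rsa_gap / 2`` from each
    ROI's facing edge. The anchor path is the hand ROI's most lateral vertex
    column, its midpoint the middle path vertex (lower index on ties).
    """
    if rsa_gap < 0:
        raise InvalidParameterError("rsa_gap must be non-negative")
    x = mesh.axis
    extent = x.max() - x.min()
    if hand_extent + face_extent > extent + 1e-9:
        raise InvalidGeometryError(
            f"hand_extent + face_extent ({hand_extent + face_extent}) exceeds "
            f"patch lateral extent ({extent})")

    tol = 1e-9
    hand = np.flatnonzero(x < x.min() + hand_extent - tol)
    face = np.flatnonzero(x >= x.max() - face_extent - tol)
    if hand.size == 0 or face.size == 0:
        raise InvalidGeometryError("hand or face ROI is empty")

    hand_xmax = x[hand].max()
    face_xmin = x[face].min()
    hand_trimmed = hand[x[hand] <= hand_xmax - rsa_gap / 2.0 + tol]
    face_trimmed = face[x[face] >= face_xmin + rsa_gap / 2.0 - tol]

    border = hand[np.abs(x[hand] - hand_xmax) < tol]
    # order along the second (medial) coordinate
    path = border[np.argsort(mesh.vertices[border, 1], kind="stable")]
    midpoint = int(path[(len(path) - 1) // 2])

    return RoiSet(
        hand=np.sort(hand),
        face=np.sort(face),
        s1_combined=np.sort(np.union1d(hand, face)),
        hand_trimmed=np.sort(hand_trimmed),
        face_trimmed=np.sort(face_trimmed),
        anchor_path=path,
        anchor_midpoint=midpoint,
    )


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------

@dataclass
class MeshSpec:
    n_medial: int = 15
    n_lateral: int = 31
    spacing: float = 1.0
    hand_extent: float = 10.0
    face_extent: float = 20.0
    rsa_gap: float = 4.0

    def build(self) -> Tuple[SurfaceMesh, RoiSet]:
        mesh = build_flat_patch_mesh(self.n_medial, self.n_lateral, self.spacing)
        rois = define_rois(mesh, self.hand_extent, self.face_extent, self.rsa_gap)
        return mesh, rois


@dataclass
class ProtocolSpec:
    """Block-design protocol; defaults mirror the acquisition template."""

    block_s: float = 8.0
    repeats: int = 4
    baseline_blocks: int = 5
    runs: int = 3
    tr: float = 1.45
    n_volumes: int = 172


@dataclass
class NoiseSpec:
    temporal_sd: float = 0.5
    ar1: float = 0.3
    smooth_fwhm: float = 2.0


@dataclass
class CohortSpec:
    """Everything needed to generate the cohort deterministically."""

    groups: Dict[str, int] = field(
        default_factory=lambda: {"controls": 22, "amputees": 17, "one_handers": 21})
    conditions: Tuple[str, ...] = FACE_CONDITIONS
    include_thumb: bool = False
    hemispheres: Tuple[str, str] = HEMISPHERES
    mesh: MeshSpec = field(default_factory=MeshSpec)
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    # lateral offset (mm) of each condition's blob centre from the hand
    # border anchor; upright map => forehead nearest the border
    blob_centres: Dict[str, float] = field(
        default_factory=lambda: {"forehead": 3.0, "nose": 8.0, "lips": 13.0,
                                 "tongue": 18.0, "thumb": -5.0})
    blob_width: float = 3.0
    blob_amplitude: float = 1.0
    # per group, per condition, CoG displacement toward (+) / away (-) from
    # the hand border, applied to the deprived hemisphere
    shift_params: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {"controls": {}, "amputees": {},
                                 "one_handers": {"lips": 5.0, "tongue": 3.0,
                                                 "forehead": -4.0}})
    jitter_sd: float = 1.0
    seed: int = 0

    @property
    def analysis_conditions(self) -> Tuple[str, ...]:
        conds = tuple(self.conditions)
        if self.include_thumb and "thumb" not in conds:
            conds = conds + ("thumb",)
        return conds

    def with_(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def generate_subject_truth(spec: CohortSpec, group: str, subject_seed: int,
                           mesh: Optional[SurfaceMesh] = None,
                           rois: Optional[RoiSet] = None,
                           jitter: bool = True,
                           ) -> Dict[str, Dict[str, np.ndarray]]:
    """Per-hemisphere, per-condition true activation pattern.

    Each condition's truth is an isotropic planar Gaussian bump centred on the
    configured medial->lateral offset from the hand-border anchor, displaced
    in the deprived hemisphere by the group's shift toward (+x decrease) the
    border, plus per-subject jitter shared across hemispheres.
    """
    if group not in spec.groups:
        raise InvalidParameterError(f"unknown group {group!r}")
    if mesh is None or rois is None:
        mesh, rois = spec.mesh.build()

    rng = np.random.default_rng(subject_seed)
    anchor_x = float(mesh.axis[rois.anchor_midpoint])
    mid_y = float(mesh.vertices[:, 1].mean())
    shifts = spec.shift_params.get(group, {})
    sigma = spec.blob_width

    truths: Dict[str, Dict[str, np.ndarray]] = {}
    jit = {c: (rng.normal(0.0, spec.jitter_sd, size=2) if jitter and spec.jitter_sd > 0
               else np.zeros(2))
           for c in spec.analysis_conditions}
    for hemi in spec.hemispheres:
        per_cond: Dict[str, np.ndarray] = {}
        for cond in spec.analysis_conditions:
            cx = anchor_x + spec.blob_centres[cond] + jit[cond][0]
            cy = mid_y + jit[cond][1]
            if hemi == "deprived":
                cx -= shifts.get(cond, 0.0)
            d2 = (mesh.axis - cx) ** 2 + (mesh.vertices[:, 1] - cy) ** 2
            per_cond[cond] = spec.blob_amplitude * np.exp(-d2 / (2.0 * sigma ** 2))
        truths[hemi] = per_cond
    return truths


def planar_cog(pattern: np.ndarray, mesh: SurfaceMesh) -> float:
    """Amplitude-weighted mean medial->lateral coordinate of a pattern."""
    total = pattern.sum()
    if total <= 0:
        raise InvalidParameterError("pattern has no mass")
    return float((pattern * mesh.axis).sum() / total)


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

@dataclass
class Run:
    """One functional run: vertex x time data plus its event list."""

    data: np.ndarray                      # (vertices, volumes)
    tr: float
    events: List[Tuple[str, float, float]]  # (condition, onset s, duration s)
    subject_id: str = ""
    hemisphere: str = ""
    run_index: int = 0

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


def _smoothing_iterations(fwhm: float, spacing: float) -> int:
    # iterated neighbour averaging: each pass adds ~spacing^2/2 of spatial
    # variance; match the variance of a Gaussian with the requested FWHM
    if fwhm <= 0:
        return 0
    target_var = (fwhm / 2.3548) ** 2
    return max(1, int(round(2.0 * target_var / spacing ** 2)))


def smooth_on_mesh(values: np.ndarray, mesh: SurfaceMesh, iterations: int) -> np.ndarray:
    """Iterated neighbour averaging of per-vertex values (last axis = vertex)."""
    if iterations <= 0:
        return values
    adj = (mesh.adjacency > 0).astype(float)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    out = values
    for _ in range(iterations):
        neighbour_mean = (out @ adj.T) / deg
        out = 0.5 * out + 0.5 * neighbour_mean
    return out


def _block_events(spec: CohortSpec, rng: np.random.Generator) -> List[Tuple[str, float, float]]:
    blocks: List[str] = []
    for cond in spec.analysis_conditions:
        blocks.extend([cond] * spec.protocol.repeats)
    blocks.extend(["baseline"] * spec.protocol.baseline_blocks)
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]
    events = []
    t = 0.0
    for b in blocks:
        if b != "baseline":
            events.append((b, t, spec.protocol.block_s))
        t += spec.protocol.block_s
    return events


def generate_run_timeseries(truth: Dict[str, np.ndarray], spec: CohortSpec,
                            run_index: int, seed: int,
                            mesh: Optional[SurfaceMesh] = None,
                            subject_id: str = "", hemisphere: str = "") -> Run:
    """Simulate one run: HRF-convolved block signal plus AR(1), spatially
    smoothed noise. Bit-identical for identical (truth, spec, run_index, seed).
    """
    from .glm import build_design_matrix  # local import to avoid a cycle

    if run_index >= spec.protocol.runs:
        raise InvalidParameterError("run_index out of range")
    if mesh is None:
        mesh, _ = spec.mesh.build()

    proto = spec.protocol
    n_vol = proto.n_volumes
    run_duration = n_vol * proto.tr
    rng = np.random.default_rng(seed)
    events = _block_events(spec, rng)
    if events and events[-1][1] + events[-1][2] > run_duration + 1e-9:
        raise InvalidParameterError(
            "protocol blocks do not fit in the configured number of volumes")

    design = build_design_matrix(events, proto.tr, n_vol,
                                 conditions=spec.analysis_conditions)
    cond_cols = design.matrix[:, :len(spec.analysis_conditions)]  # (T, C)
    truth_mat = np.vstack([truth[c] for c in spec.analysis_conditions])  # (C, V)
    data = (cond_cols @ truth_mat).T  # (V, T)

    noise = spec.noise
    if noise.temporal_sd > 0:
        innov = rng.standard_normal((mesh.n_vertices, n_vol))
        if abs(noise.ar1) > 0:
            e = sp_signal.lfilter([1.0], [1.0, -noise.ar1], innov, axis=1)
            e *= np.sqrt(1.0 - noise.ar1 ** 2)  # marginal sd -> 1 (stationary)
        else:
            e = innov
        e *= noise.temporal_sd
        iters = _smoothing_iterations(noise.smooth_fwhm, spec.mesh.spacing)
        if iters:
            e = smooth_on_mesh(e.T, mesh, iters).T
        data = data + e

    return Run(data=data, tr=proto.tr, events=events, subject_id=subject_id,
               hemisphere=hemisphere, run_index=run_index)


# ---------------------------------------------------------------------------
# questionnaire + cohort bundle
# ---------------------------------------------------------------------------

TABLE1_COLUMNS = [
    "Participants", "Age", "Gender",
    "Handedness (prior to amputation for amputees)", "Affected limb",
    "Level of limb deficiency", "Years since amputation",
    "PLS intensity", "PLS frequency", "Chronic PLS",
    "PLP intensity", "PLP frequency", "Chronic PLP", "Cause of amputation",
]


@dataclass
class Subject:
    subject_id: str
    group: str
    truth: Dict[str, Dict[str, np.ndarray]]
    runs: Dict[str, List[Run]]            # hemisphere -> runs


@dataclass
class CohortBundle:
    spec: CohortSpec
    mesh: SurfaceMesh
    rois: RoiSet
    subjects: List[Subject]
    participants: pd.DataFrame            # Table 1-style columns

    def by_group(self, group: str) -> List[Subject]:
        return [s for s in self.subjects if s.group == group]


def _questionnaire_row(subject_id: str, group: str, rng: np.random.Generator) -> dict:
    from .phantom import chronic_score

    age = int(np.clip(round(rng.normal(48, 12)), 20, 75))
    gender = rng.choice(["M", "F"])
    row = {c: "" for c in TABLE1_COLUMNS}
    row.update({"Participants": subject_id, "Age": age, "Gender": gender,
                "Handedness (prior to amputation for amputees)": rng.choice(["R", "L"], p=[0.85, 0.15])})
    if group in ("amputees", "one_handers"):
        row["Affected limb"] = rng.choice(["R", "L"])
        row["Level of limb deficiency"] = int(rng.choice([1, 2]))
    if group == "amputees":
        row["Years since amputation"] = int(rng.integers(1, 45))
        for prefix in ("PLS", "PLP"):
            intensity = float(rng.choice([0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100]))
            freq = float(rng.integers(0, 6)) if intensity > 0 else 0.0
            score = chronic_score(intensity, freq)
            row[f"{prefix} intensity"] = intensity
            row[f"{prefix} frequency"] = freq
            row[f"Chronic {prefix}"] = score.value
        row["Cause of amputation"] = rng.choice(["Trauma", "Tumour", "Electrocution"],
                                                p=[0.8, 0.1, 0.1])
    return row


def generate_cohort(spec: CohortSpec) -> CohortBundle:
    """Generate the full cohort: a pure function of the spec (incl. its seed)."""
    mesh, rois = spec.mesh.build()
    root = np.random.SeedSequence(spec.seed)

    subjects: List[Subject] = []
    rows: List[dict] = []
    for g_idx, (group, count) in enumerate(spec.groups.items()):
        if group not in _ID_PREFIX:
            raise InvalidParameterError(f"unknown group {group!r}")
        for s_idx in range(count):
            child = np.random.SeedSequence(entropy=root.entropy,
                                           spawn_key=(g_idx, s_idx))
            seeds = child.generate_state(2 + 2 * spec.protocol.runs)
            subject_id = f"{_ID_PREFIX[group]}{s_idx + 1:02d}"
            truth = generate_subject_truth(spec, group, int(seeds[0]),
                                           mesh=mesh, rois=rois)
            runs: Dict[str, List[Run]] = {}
            for h_idx, hemi in enumerate(spec.hemispheres):
                runs[hemi] = [
                    generate_run_timeseries(
                        truth[hemi], spec, r,
                        int(seeds[2 + h_idx * spec.protocol.runs + r]),
                        mesh=mesh, subject_id=subject_id, hemisphere=hemi)
                    for r in range(spec.protocol.runs)
                ]
            subjects.append(Subject(subject_id=subject_id, group=group,
                                    truth=truth, runs=runs))
            q_rng = np.random.default_rng(int(seeds[1]))
            row = _questionnaire_row(subject_id, group, q_rng)
            row["__group"] = group
            rows.append(row)

    participants = pd.DataFrame(rows)
    participants = participants.rename(columns={"__group": "Group"})
    return CohortBundle(spec=spec, mesh=mesh, rois=rois, subjects=subjects,
                        participants=participants)
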