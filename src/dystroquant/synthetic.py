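"""Ground-truthed simulators for the three assay types the pipeline analyses.

Every downstream stage of the package is verifiable without external data:
this module renders fluorescence micrographs with known nucleus positions
and marker masks, linear product-accumulation plate-reader kinetics with
and without inhibitor, and log-normal peptide-abundance tables with planted
differential proteins — each carrying an exact record of its ground truth.

The generators are fully deterministic: the same parameters and seed give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imaging import MyogenesisIndices

GENOTYPES = ("WT", "Dys")
AGE_GROUPS = ("3", "7.5")          # months

#: the study's hallmark effect: a leukocyte-elastase-inhibitor-like protein
#: enriched ~6-fold in young and ~7-fold in older dystrophic muscle
SERPIN_LIKE_SPEC = (("P0001", "3", 6.0), ("P0001", "7.5", 7.0))


class PlacementError(RuntimeError):
    """Scene geometry could not be placed within the retry budget."""


# ---------------------------------------------------------------------------
# Micrograph simulation
# ---------------------------------------------------------------------------

@dataclass
class ImageSimParams:
    """Parameters of a simulated two-channel myogenesis micrograph.

    Geometry is in pixels and intensities on the 8-bit scale (the 16-bit
    rendering rescales both signal and noise).  ``frac_touching_pairs`` is
    the fraction of marker-free nuclei laid down as touching pairs at a
    centre distance of 1.6 radii, which merge under thresholding and so
    exercise the watershed split.
    """

    image_height_px: int = 256
    image_width_px: int = 256
    n_nuclei: int = 40
    nucleus_radius_px: float = 6.0
    nucleus_radius_sd_px: float = 0.8
    frac_touching_pairs: float = 0.2
    n_myotubes: int = 2
    nuclei_per_myotube: int = 4
    myotube_length_px: float = 150.0
    myotube_width_px: float = 26.0
    n_mono_myhc_cells: int = 3
    noise_sd: float = 6.0
    background_level: float = 20.0
    foreground_level: float = 180.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_nuclei < 0 or self.n_myotubes < 0 or self.n_mono_myhc_cells < 0:
            raise ValueError("object counts must be non-negative")
        if not (0.0 <= self.frac_touching_pairs <= 1.0):
            raise ValueError("frac_touching_pairs must lie in [0, 1]")
        if self.foreground_level <= self.background_level:
            raise ValueError("foreground_level must exceed background_level")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        assigned = self.n_myotubes * self.nuclei_per_myotube + self.n_mono_myhc_cells
        if self.n_nuclei < assigned:
            raise ValueError(
                f"n_nuclei={self.n_nuclei} cannot cover {assigned} nuclei "
                "required by myotubes and mononucleated marker+ cells")
        span = min(self.image_height_px, self.image_width_px)
        if self.n_myotubes and self.myotube_length_px > span - 8:
            raise ValueError("myotube does not fit inside the image")
        if self.nucleus_radius_px <= 0 or (self.n_myotubes or self.n_mono_myhc_cells
                                           or self.n_nuclei) and \
                6 * self.nucleus_radius_px > span:
            raise ValueError("nucleus geometry does not fit inside the image")


@dataclass
class SyntheticGroundTruth:
    """Exact record of a simulated scene.

    ``memberships[i]`` is the marker-object id (1..K, 0 = none) whose
    component contains nucleus ``i``'s centroid by construction;
    ``true_indices`` is recomputable from it by enumeration.
    """

    nucleus_centroids: np.ndarray          # (n, 2) float (row, col), 0-based
    nucleus_radii: np.ndarray              # (n,)
    memberships: np.ndarray                # (n,) int object ids, 0 = none
    mono_object_ids: tuple[int, ...]       # object ids that are mononucleated cells
    touching_pairs: tuple[tuple[int, int], ...]
    nucleus_mask: np.ndarray               # bool
    marker_mask: np.ndarray                # bool
    marker_object_map: np.ndarray          # int label map of intended objects
    true_indices: MyogenesisIndices
    channel_stack_16bit: np.ndarray        # (2, H, W) uint16: nuclei, marker
    params: ImageSimParams


def indices_from_memberships(
    memberships: np.ndarray,
    marker_area_px: int,
    image_area_px: int,
    min_nuclei_per_myotube: int = 2,
) -> MyogenesisIndices:
    """Brute-force enumeration of the myogenesis indices from memberships."""
    memberships = np.asarray(memberships, dtype=int)
    total = int(memberships.size)
    in_marker = memberships[memberships > 0]
    nuclei_in_marker = int(in_marker.size)
    if nuclei_in_marker:
        counts = np.bincount(in_marker)
        myotube_ids = np.flatnonzero(counts >= min_nuclei_per_myotube)
        myotube_ids = myotube_ids[myotube_ids > 0]
        myotube_nuclei = int(counts[myotube_ids].sum())
        myotube_count = int(myotube_ids.size)
    else:
        myotube_nuclei = myotube_count = 0
    flags = []
    di = nuclei_in_marker / total if total else 0.0
    if total == 0:
        flags.append("no_nuclei")
    fi = myotube_nuclei / nuclei_in_marker if nuclei_in_marker else 0.0
    if nuclei_in_marker == 0:
        flags.append("no_marker_cells")
    return MyogenesisIndices(
        total_nuclei=total,
        nuclei_in_marker=nuclei_in_marker,
        myotube_nuclei=myotube_nuclei,
        marker_positive_cell_count=nuclei_in_marker,
        myotube_count=myotube_count,
        myotube_area_px=marker_area_px,
        marker_area_px=marker_area_px,
        marker_area_fraction=marker_area_px / image_area_px,
        differentiation_index=di,
        fusion_index=fi,
        flags=tuple(flags),
    )


def _capsule_mask(shape, p0, p1, half_width) -> np.ndarray:
    """Boolean mask of all pixels within half_width of the segment p0-p1."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    d = np.array(p1) - np.array(p0)
    L2 = float(d @ d)
    vr = rr - p0[0]
    vc = cc - p0[1]
    t = np.clip((vr * d[0] + vc * d[1]) / L2, 0.0, 1.0) if L2 > 0 else 0.0
    dr = vr - t * d[0]
    dc = vc - t * d[1]
    return dr * dr + dc * dc <= half_width * half_width


def _ellipse_mask(shape, center, a, b, phi) -> np.ndarray:
    r0, c0 = center
    rad = int(np.ceil(max(a, b))) + 1
    rlo, rhi = max(0, int(r0) - rad), min(shape[0], int(r0) + rad + 1)
    clo, chi = max(0, int(c0) - rad), min(shape[1], int(c0) + rad + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr = rr - r0
    dc = cc - c0
    u = dr * np.cos(phi) + dc * np.sin(phi)
    v = -dr * np.sin(phi) + dc * np.cos(phi)
    out = np.zeros(shape, bool)
    out[rlo:rhi, clo:chi] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return out


def _place_marker_objects(params: ImageSimParams, rng) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Lay down myotube capsules and mononucleated marker+ discs, disjoint."""
    H, W = params.image_height_px, params.image_width_px
    marker = np.zeros((H, W), bool)
    objmap = np.zeros((H, W), np.int32)
    objects: list[dict] = []
    gap = 8  # minimum pixel gap between marker components

    def try_place(make_mask, kind, budget=300):
        for _ in range(budget):
            cand, meta = make_mask()
            if cand is None:
                continue
            if marker.any():
                dilated = ndi.binary_dilation(cand, iterations=gap)
                if (dilated & marker).any():
                    continue
            oid = len(objects) + 1
            marker[cand] = True
            objmap[cand] = oid
            objects.append({"id": oid, "kind": kind, **meta})
            return
        raise PlacementError(f"could not place {kind} within {budget} tries")

    half_w = params.myotube_width_px / 2.0
    margin = half_w + 3.0
    for _ in range(params.n_myotubes):
        def make_tube():
            theta = rng.uniform(0, np.pi)
            d = np.array([np.sin(theta), np.cos(theta)])
            half = params.myotube_length_px / 2.0
            lo_r = margin + abs(d[0]) * half
            lo_c = margin + abs(d[1]) * half
            if lo_r >= H - lo_r or lo_c >= W - lo_c:
                return None, {}
            ctr = np.array([rng.uniform(lo_r, H - 1 - lo_r),
                            rng.uniform(lo_c, W - 1 - lo_c)])
            p0, p1 = ctr - half * d, ctr + half * d
            return _capsule_mask((H, W), p0, p1, half_w), \
                {"p0": p0, "p1": p1, "half_width": half_w}
        try_place(make_tube, "myotube")

    mono_r = max(params.nucleus_radius_px * 1.8, params.nucleus_radius_px + 4)
    for _ in range(params.n_mono_myhc_cells):
        def make_mono():
            ctr = (rng.uniform(mono_r + 2, H - 1 - mono_r - 2),
                   rng.uniform(mono_r + 2, W - 1 - mono_r - 2))
            return _ellipse_mask((H, W), ctr, mono_r, mono_r, 0.0), {"center": ctr}
        try_place(make_mono, "mono")

    return marker, objmap, objects


def _place_nuclei(params: ImageSimParams, rng, marker, objects):
    """Choose nucleus centroids, radii, memberships and touching pairs."""
    H, W = params.image_height_px, params.image_width_px
    r_mean, r_sd = params.nucleus_radius_px, params.nucleus_radius_sd_px
    min_sep = 2.8 * r_mean
    centroids: list[np.ndarray] = []
    radii: list[float] = []
    memberships: list[int] = []
    pairs: list[tuple[int, int]] = []

    def draw_radius():
        return float(np.clip(rng.normal(r_mean, r_sd), 3.0, r_mean + 3 * r_sd))

    def far_from_others(p, sep):
        return all(np.hypot(*(p - q)) >= sep for q in centroids)

    # distance of every pixel to the nearest marker pixel (for exclusion)
    if marker.any():
        dist_to_marker = ndi.distance_transform_edt(~marker)
    else:
        dist_to_marker = np.full((H, W), np.inf)

    def marker_clearance(p):
        r = int(np.clip(np.rint(p[0]), 0, H - 1))
        c = int(np.clip(np.rint(p[1]), 0, W - 1))
        return dist_to_marker[r, c]

    budget = 400

    # nuclei inside myotubes: spread along the capsule axis, clear of the rim
    for obj in objects:
        if obj["kind"] != "myotube":
            continue
        p0, p1, hw = obj["p0"], obj["p1"], obj["half_width"]
        axis = p1 - p0
        for _ in range(params.nuclei_per_myotube):
            r = draw_radius()
            lat_max = max(hw - r - 2.0, 0.0)
            pad = (r + 3.0) / np.hypot(*axis)
            for attempt in range(budget):
                t = rng.uniform(pad, 1 - pad)
                lat = rng.uniform(-lat_max, lat_max)
                nrm = np.array([-axis[1], axis[0]]) / np.hypot(*axis)
                p = p0 + t * axis + lat * nrm
                if far_from_others(p, min_sep):
                    break
            else:
                raise PlacementError("could not place a myotube nucleus")
            centroids.append(p)
            radii.append(r)
            memberships.append(obj["id"])

    # one nucleus at the centre of each mononucleated marker+ cell
    for obj in objects:
        if obj["kind"] != "mono":
            continue
        centroids.append(np.asarray(obj["center"], float))
        radii.append(draw_radius())
        memberships.append(obj["id"])

    n_outside = params.n_nuclei - len(centroids)
    n_pairs = int(params.frac_touching_pairs * n_outside // 2)

    def sample_outside(r, extra=0.0):
        for attempt in range(budget):
            p = np.array([rng.uniform(r + 2, H - 1 - r - 2),
                          rng.uniform(r + 2, W - 1 - r - 2)])
            if marker_clearance(p) >= r + 6.0 + extra and far_from_others(p, min_sep + extra):
                return p
        raise PlacementError("could not place a marker-free nucleus")

    for _ in range(n_pairs):
        r = draw_radius()
        ctr = sample_outside(r, extra=1.6 * r)
        phi = rng.uniform(0, np.pi)
        off = 0.8 * r * np.array([np.sin(phi), np.cos(phi)])
        a, b = ctr + off, ctr - off
        i = len(centroids)
        centroids.extend([a, b])
        radii.extend([r, r])
        memberships.extend([0, 0])
        pairs.append((i, i + 1))

    for _ in range(n_outside - 2 * n_pairs):
        r = draw_radius()
        p = sample_outside(r)
        centroids.append(p)
        radii.append(r)
        memberships.append(0)

    cents = np.array(centroids).reshape(-1, 2)
    return cents, np.array(radii), np.array(memberships, int), tuple(pairs)


def simulate_image(params: ImageSimParams) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Render a two-channel myogenesis scene with exact ground truth.

    Returns an 8-bit RGB image (red empty background, green = marker,
    blue = nuclei) and the ground-truth record, which also carries a
    2-plane 16-bit rendering of the same scene (independent noise draw,
    signal and noise scaled by 257).

    Nuclei are filled ellipses with axis ratio in [0.7, 1.0]; touching
    pairs are circles at centre distance 1.6 r.  Noise is additive Gaussian
    clipped to the valid intensity range.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    H, W = params.image_height_px, params.image_width_px

    marker, objmap, objects = _place_marker_objects(params, rng)
    cents, radii, memberships, pairs = _place_nuclei(params, rng, marker, objects)

    nucleus_mask = np.zeros((H, W), bool)
    pair_members = {i for ab in pairs for i in ab}
    for i, (p, r) in enumerate(zip(cents, radii)):
        if i in pair_members:
            a = b = r                               # circles keep 1.6 r exact
            phi = 0.0
        else:
            ratio = rng.uniform(0.7, 1.0)
            a, b = r / np.sqrt(ratio), r * np.sqrt(ratio)
            phi = rng.uniform(0, np.pi)
        nucleus_mask |= _ellipse_mask((H, W), p, a, b, phi)

    bg, fg = params.background_level, params.foreground_level
    base_nuc = np.where(nucleus_mask, fg, bg).astype(float)
    base_mar = np.where(marker, fg, bg).astype(float)

    def render(base, scale, top, dtype):
        noisy = base * scale + rng.normal(0.0, params.noise_sd * scale, base.shape)
        return np.clip(np.rint(noisy), 0, top).astype(dtype)

    rgb = np.zeros((H, W, 3), np.uint8)
    rgb[..., 1] = render(base_mar, 1.0, 255, np.uint8)
    rgb[..., 2] = render(base_nuc, 1.0, 255, np.uint8)
    stack16 = np.stack([render(base_nuc, 257.0, 65535, np.uint16),
                        render(base_mar, 257.0, 65535, np.uint16)])

    truth = indices_from_memberships(memberships, int(marker.sum()), H * W)
    gt = SyntheticGroundTruth(
        nucleus_centroids=cents,
        nucleus_radii=radii,
        memberships=memberships,
        mono_object_ids=tuple(o["id"] for o in objects if o["kind"] == "mono"),
        touching_pairs=pairs,
        nucleus_mask=nucleus_mask,
        marker_mask=marker,
        marker_object_map=objmap,
        true_indices=truth,
        channel_stack_16bit=stack16,
        params=params,
    )
    return rgb, gt


# ---------------------------------------------------------------------------
# Plate-reader kinetics simulation
# ---------------------------------------------------------------------------

@dataclass
class KineticSimParams:
    """Linear product-accumulation kinetics with and without inhibitor.

    Defaults mirror the assay design the pipeline targets: readings every
    15 min over 3 h (13 timepoints) in 3 technical replicates.  The sample
    signal is ``baseline + rate·t·(1 − inhibition_fraction) + noise``; the
    blank is ``baseline + noise``.  Signals are arbitrary units (AU).
    """

    n_timepoints: int = 13
    dt_min: float = 15.0
    baseline: float = 50.0
    rate_uninhibited: float = 2.0
    inhibition_fraction: float = 0.5
    noise_sd: float = 2.0
    n_technical_replicates: int = 3
    condition: str = "sample"
    inhibitor_name: str = "cocktail"
    seed: int = 0

    def validate(self) -> None:
        if self.n_timepoints < 1 or self.dt_min <= 0:
            raise ValueError("time grid must be non-empty and increasing")
        if not (0.0 <= self.inhibition_fraction <= 1.0):
            raise ValueError("inhibition_fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.n_technical_replicates < 1:
            raise ValueError("invalid noise_sd or replicate count")


def simulate_kinetics(params: KineticSimParams) -> pd.DataFrame:
    """Simulate a plate of kinetic series as a tidy table.

    Returns a DataFrame with columns
    ``well, condition, inhibitor, replicate, time_min, signal`` containing
    uninhibited sample wells (``inhibitor="none"``), inhibited sample wells
    (``inhibitor=params.inhibitor_name``) and buffer-only blank wells
    (``condition="blank"``), each in ``n_technical_replicates`` copies.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    t = np.arange(params.n_timepoints) * params.dt_min

    rows = []
    layout = [
        (params.condition, "none", params.rate_uninhibited),
        (params.condition, params.inhibitor_name,
         params.rate_uninhibited * (1.0 - params.inhibition_fraction)),
        ("blank", "none", 0.0),
    ]
    for cond, inhibitor, rate in layout:
        for rep in range(1, params.n_technical_replicates + 1):
            signal = params.baseline + rate * t
            signal = signal + rng.normal(0.0, params.noise_sd, t.size)
            well = f"{cond}-{inhibitor}-r{rep}"
            rows.append(pd.DataFrame({
                "well": well, "condition": cond, "inhibitor": inhibitor,
                "replicate": rep, "time_min": t, "signal": signal,
            }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Label-free proteomics simulation
# ---------------------------------------------------------------------------

@dataclass
class ProteomeSimParams:
    """Log-normal peptide-abundance tables over a 2x2 genotype-by-age design.

    Defaults emulate the study scale: 540 quantifiable proteins, five
    biological replicates per genotype per age group, 20% abundance CV.
    ``differential_spec`` plants fold changes: each entry
    ``(protein_id, age_group, fold)`` scales that protein's abundance in
    the Dys runs of that age group.  ``run_scale_factors`` are per-run
    multiplicative biases (drawn log-normally when ``None``) that exercise
    the normalization stage.  Peptide charges are drawn from 1..8 so the
    2+..7+ charge filter is exercised.

    ``missing_rate`` defaults to 0 because the upstream quantification
    style emulated here (retention-time-aligned feature matching) yields
    essentially complete abundance tables; raise it to probe robustness
    of normalization and rollup to dropout.
    """

    n_proteins: int = 540
    peptides_per_protein_mean: float = 4.0
    frac_shared_peptides: float = 0.05
    n_replicates_per_group: int = 5
    differential_spec: Sequence[tuple[str, str, float]] = ()
    abundance_cv: float = 0.2
    missing_rate: float = 0.0
    run_scale_factors: Sequence[float] | None = None
    run_scale_sd_log: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1 or self.peptides_per_protein_mean < 1:
            raise ValueError("need at least one protein with one peptide")
        if self.n_replicates_per_group < 2:
            raise ValueError("design needs >=2 replicates per cell")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")
        if not (0.0 <= self.frac_shared_peptides <= 1.0):
            raise ValueError("frac_shared_peptides must lie in [0, 1]")
        if self.abundance_cv < 0:
            raise ValueError("abundance_cv must be non-negative")
        for pid, age, fold in self.differential_spec:
            if fold <= 0:
                raise ValueError(f"fold change for {pid} must be positive")
            if age not in AGE_GROUPS:
                raise ValueError(f"unknown age group {age!r}")


_CHARGE_VALUES = np.arange(1, 9)
_CHARGE_PROBS = np.array([0.05, 0.30, 0.30, 0.15, 0.08, 0.05, 0.04, 0.03])


def make_run_design(n_replicates_per_group: int) -> pd.DataFrame:
    """The 2x2 genotype-by-age run design table."""
    rows = [
        {"run_id": f"{g}_{a}m_r{r}", "genotype": g, "age_group": a, "replicate": r}
        for a in AGE_GROUPS for g in GENOTYPES
        for r in range(1, n_replicates_per_group + 1)
    ]
    return pd.DataFrame(rows)


def simulate_peptide_table(
    params: ProteomeSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a peptide-level LC-MS quantification table.

    Returns ``(peptides, design, truth)``:

    * ``peptides`` — columns ``peptide, charge, accessions, run_id,
      abundance`` (accessions ``;``-joined; shared peptides carry two);
    * ``design`` — columns ``run_id, genotype, age_group, replicate``;
    * ``truth`` — the planted differential proteins
      (``protein, age_group, fold_change``).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    design = make_run_design(params.n_replicates_per_group)
    runs = design["run_id"].to_numpy()
    n_runs = runs.size

    prot_ids = np.array([f"P{i + 1:04d}" for i in range(params.n_proteins)])
    base_log10 = rng.normal(6.0, 0.6, params.n_proteins)

    n_pep = 1 + rng.poisson(params.peptides_per_protein_mean - 1.0,
                            params.n_proteins)
    # planted differential proteins are quantifiable by construction: they
    # carry at least 3 peptides and never enter the shared-peptide pool
    planted_ids = sorted({pid for pid, _, _ in params.differential_spec})
    planted_rows = np.array(
        [np.flatnonzero(prot_ids == pid)[0] for pid in planted_ids
         if (prot_ids == pid).any()], dtype=int)
    if planted_rows.size:
        n_pep[planted_rows] = np.maximum(n_pep[planted_rows], 3)
    pep_protein = np.repeat(np.arange(params.n_proteins), n_pep)
    total = pep_protein.size
    pep_ids = np.array([f"PEP{i + 1:06d}" for i in range(total)])
    charges = rng.choice(_CHARGE_VALUES, size=total, p=_CHARGE_PROBS)
    efficiency = rng.lognormal(0.0, 0.5, total)

    # fold-change matrix (protein x run)
    fold = np.ones((params.n_proteins, n_runs))
    idx = {pid: i for i, pid in enumerate(prot_ids)}
    for pid, age, f in params.differential_spec:
        if pid not in idx:
            raise ValueError(f"differential protein {pid!r} not in the simulation")
        sel = ((design["genotype"] == "Dys") & (design["age_group"] == age)).to_numpy()
        fold[idx[pid], sel] = f

    if params.run_scale_factors is not None:
        scale = np.asarray(params.run_scale_factors, float)
        if scale.size != n_runs:
            raise ValueError(f"expected {n_runs} run scale factors")
    else:
        scale = rng.lognormal(0.0, params.run_scale_sd_log, n_runs)

    sigma = np.sqrt(np.log1p(params.abundance_cv ** 2))
    mean = (10.0 ** base_log10)[pep_protein, None] * efficiency[:, None] \
        * fold[pep_protein, :] * scale[None, :]
    abundance = mean * np.exp(rng.normal(0.0, sigma, (total, n_runs)))

    # shared peptides carry a second accession and are excluded from rollup
    n_shared = int(round(params.frac_shared_peptides * total))
    shareable = np.flatnonzero(~np.isin(pep_protein, planted_rows))
    n_shared = min(n_shared, shareable.size)
    shared_idx = rng.choice(shareable, size=n_shared, replace=False) if n_shared else np.array([], int)
    accessions = prot_ids[pep_protein].astype(object)
    for i in shared_idx:
        other = int(rng.integers(params.n_proteins - 1))
        if other >= pep_protein[i]:
            other += 1
        accessions[i] = f"{accessions[i]};{prot_ids[other]}"

    present = rng.random((total, n_runs)) >= params.missing_rate
    pi, ri = np.nonzero(present)
    peptides = pd.DataFrame({
        "peptide": pep_ids[pi],
        "charge": charges[pi],
        "accessions": accessions[pi],
        "run_id": runs[ri],
        "abundance": abundance[pi, ri],
    })
    truth = pd.DataFrame(
        [{"protein": pid, "age_group": age, "fold_change": f}
         for pid, age, f in params.differential_spec],
        columns=["protein", "age_group", "fold_change"],
    )
    return peptides, design, truth
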