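"""Whole-subject angiogram synthesis and seeded cohorts.

A synthetic subject is: schematic anatomy labels, a calibrated vessel
forest, spoiled-GRE signal per compartment with partial-volume mixing of
blood into tissue, optional blood-pool contrast, and Rician noise.  The
record carries machine-readable ground truth (occupancy grid and per-ROI
vascular fractions) that the analysis modules are expected to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from cerevasc.grids import LabelVolume, Volume
from cerevasc import calibration
from cerevasc.synthetic.anatomy import LABEL_IDS, brain_labels
from cerevasc.synthetic.mri import (
    ContrastParams,
    ScanParams,
    TissueParams,
    add_rician_noise,
    default_noise_sigma,
    spgre_signal,
    tof_boost_factor,
)
from cerevasc.synthetic.seeds import substream
from cerevasc.synthetic.tree import generate_vessel_tree_with_occupancy, rasterize_tree, VesselTree

__all__ = [
    "PhantomSpec",
    "SubjectRecord",
    "default_young_targets",
    "resolve_roi_targets",
    "synthesize_subject",
    "synthesize_cohort",
]

#: ROIs that receive their own vessel forests, besides the parenchyma remainder.
SUB_ROIS = (
    "cerebral_cortex",
    "cerebellar_cortex",
    "entorhinal_cortex",
    "hippocampus",
    "striatum",
)


def default_young_targets() -> dict[str, float]:
    """Per-ROI vascular volume fraction targets (%) for a young-adult brain."""
    return {
        "whole_brain": calibration.acbv_mean("whole_brain", "2-4"),
        **{roi: calibration.acbv_mean(roi, "2-4") for roi in SUB_ROIS},
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to synthesize one angiogram subject.

    ``target_fraction_by_roi`` gives vascular volume fractions in percent;
    a ``whole_brain`` entry is a constraint on the whole-brain union and is
    satisfied by solving for the implied fraction of the parenchyma
    remainder.  ``noise_sigma=None`` means calibrate the noise so the
    post-contrast vascular SNR hits its published target.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    scan: ScanParams = field(default_factory=ScanParams)
    tissue: TissueParams = field(default_factory=TissueParams)
    contrast: ContrastParams = field(default_factory=ContrastParams)
    noise_sigma: float | None = None
    texture_rel: float = 0.43
    target_fraction_by_roi: dict[str, float] = field(default_factory=default_young_targets)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive")
        for roi, f in self.target_fraction_by_roi.items():
            if not (0.0 <= f <= 100.0):
                raise ValueError(f"target fraction for {roi!r} outside [0, 100]")


@dataclass
class SubjectRecord:
    """One synthetic subject with its ground truth."""

    subject_id: str
    age_group: str
    volume: Volume
    labels: LabelVolume
    occupancy: np.ndarray  # partial-volume vessel occupancy in [0, 1]
    truth_mask: Volume  # occupancy >= 0.5, for display/QC
    truth_fraction_by_roi: dict[str, float]

    def __post_init__(self) -> None:
        if self.volume.shape != self.labels.shape or self.volume.shape != self.occupancy.shape:
            raise ValueError("volume, labels, and occupancy must share a grid")


def resolve_roi_targets(spec: PhantomSpec, labels: LabelVolume) -> dict[str, float]:
    """Turn the spec's targets into per-label-region targets.

    A ``whole_brain`` entry is converted into a target for the parenchyma
    remainder (every brain voxel not claimed by another targeted ROI or a
    ventricle) such that the occupancy-weighted whole-brain fraction equals
    the requested value.
    """
    targets = dict(spec.target_fraction_by_roi)
    if "whole_brain" not in targets:
        return targets
    wb = targets.pop("whole_brain")
    voxcount = {
        roi: int(np.isin(labels.labels, labels.roi_ids(roi)).sum()) for roi in targets
    }
    n_brain = int(np.isin(labels.labels, labels.roi_ids("whole_brain")).sum())
    # ventricles and any untargeted ROI carry no vessels; the parenchyma
    # remainder absorbs whatever the whole-brain constraint still requires
    n_parenchyma = int((labels.labels == LABEL_IDS["parenchyma"]).sum())
    implied = (wb * n_brain - sum(targets[r] * voxcount[r] for r in targets)) / max(
        n_parenchyma, 1
    )
    if implied < 0:
        raise ValueError(
            "whole-brain target is below the contribution of the sub-ROI targets"
        )
    targets["parenchyma"] = implied
    return targets


def truth_fractions(labels: LabelVolume, occupancy: np.ndarray) -> dict[str, float]:
    """Per-ROI vascular fraction (%) implied by the occupancy grid.

    Exactly ``100 * sum(occupancy in ROI) / (ROI voxel count)`` — the
    conservation identity the analysis is expected to recover.
    """
    out = {}
    for roi in labels.name_map:
        mask = np.isin(labels.labels, labels.roi_ids(roi))
        n = int(mask.sum())
        out[roi] = 100.0 * float(occupancy[mask].sum()) / n if n else float("nan")
    return out


def synthesize_subject(
    spec: PhantomSpec,
    age_group: str = "2-4",
    subject_id: str = "S000",
    contrast_on: bool = True,
) -> SubjectRecord:
    """Synthesize one angiogram subject from the spec.

    With ``contrast_on=False`` the blood compartment keeps its native T1
    and only large-radius segments receive the inflow (TOF) proton-density
    boost, emulating a pre-contrast acquisition.
    """
    spacing = spec.scan.spacing_mm
    labels = brain_labels(spec.shape, spacing)
    tree, occ = generate_vessel_tree_with_occupancy(spec, labels=labels)

    comp = spec.tissue
    scan = spec.scan
    base = np.zeros(spec.shape, dtype=float)
    par = spgre_signal(comp["parenchyma"].proton_density, comp["parenchyma"].t1_ms,
                       comp["parenchyma"].t2star_ms, scan)
    csf = spgre_signal(comp["csf"].proton_density, comp["csf"].t1_ms,
                       comp["csf"].t2star_ms, scan)
    bg = spgre_signal(comp["background"].proton_density, comp["background"].t1_ms,
                      comp["background"].t2star_ms, scan)
    lab = labels.labels
    ventricle_ids = labels.roi_ids("ventricular_system")
    base[lab > 0] = par
    base[np.isin(lab, ventricle_ids)] = csf
    base[lab == 0] = bg
    if spec.texture_rel > 0:
        # multiplicative tissue heterogeneity (grey/white contrast, partial
        # myelination, coil bias), modelled as a *bounded* uniform modulation
        # of the base signal: bounded so heterogeneity alone can never cross
        # the vessel threshold, unlike a Gaussian tail
        trng = substream(spec.seed, subject_id, "texture")
        modulation = 1.0 + spec.texture_rel * trng.uniform(-1.0, 1.0, size=spec.shape)
        base *= modulation

    blood = comp["blood"]
    if contrast_on:
        t1_post, t2_post = _blood_post(spec)
        s_blood = spgre_signal(blood.proton_density, t1_post, t2_post, scan)
        signal = (1.0 - occ) * base + occ * s_blood
    else:
        s_blood_pre = spgre_signal(blood.proton_density, blood.t1_ms, blood.t2star_ms, scan)
        boost = tof_boost_factor(comp, spec.contrast, scan)
        # clip the large-vessel map to the calibrated (ROI-masked) occupancy
        large = np.minimum(_large_vessel_occupancy(tree, spec, spacing), occ)
        small = np.clip(occ - large, 0.0, 1.0)
        signal = (1.0 - occ) * base + large * boost * s_blood_pre + small * s_blood_pre

    sigma = spec.noise_sigma
    if sigma is None:
        sigma = default_noise_sigma(comp, spec.contrast, scan)
    rng = substream(spec.seed, subject_id, "noise")
    noisy = add_rician_noise(signal, sigma, rng)

    volume = Volume(values=noisy, spacing=spacing)
    truth_mask = Volume(values=(occ >= 0.5).astype(np.uint8), spacing=spacing)
    return SubjectRecord(
        subject_id=subject_id,
        age_group=age_group,
        volume=volume,
        labels=labels,
        occupancy=occ,
        truth_mask=truth_mask,
        truth_fraction_by_roi=truth_fractions(labels, occ),
    )


def _blood_post(spec: PhantomSpec) -> tuple[float, float]:
    from cerevasc.synthetic.mri import apply_contrast

    blood = spec.tissue["blood"]
    return apply_contrast(blood.t1_ms, blood.t2star_ms, spec.contrast)


def _large_vessel_occupancy(
    tree: VesselTree, spec: PhantomSpec, spacing: float, radius_threshold_um: float = 150.0
) -> np.ndarray:
    large = [s for s in tree.segments if s.radius_um >= radius_threshold_um]
    if not large:
        return np.zeros(spec.shape, dtype=np.float32)
    sub = VesselTree(large, tree.domain)
    return rasterize_tree(sub, spec.shape, spacing)


def synthesize_cohort(
    n_by_group: dict[str, int] | None = None,
    targets_by_group: dict[str, dict[str, float]] | None = None,
    spread_by_group: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[SubjectRecord]:
    """Synthesize a seeded multi-age cohort.

    Defaults reproduce the study conditions: group sizes 14/12/8 for ages
    2-4, 14-16 and 24-26 months, per-ROI targets equal to the calibrated
    group means with the published SDs as between-subject spread.  Each
    subject's targets are drawn from a normal distribution truncated at
    zero; sub-seeds are derived per subject so cohorts are reproducible
    and subjects independent.
    """
    if n_by_group is None:
        n_by_group = dict(calibration.COHORT_N)
    rois = ("whole_brain",) + SUB_ROIS
    if targets_by_group is None:
        targets_by_group = {
            g: {roi: calibration.acbv_mean(roi, g) for roi in rois}
            for g in n_by_group
        }
    if spread_by_group is None:
        spread_by_group = {
            g: {roi: calibration.acbv_sd(roi, g) for roi in rois} for g in n_by_group
        }
    if base_spec is None:
        base_spec = PhantomSpec(seed=seed)

    subjects: list[SubjectRecord] = []
    counter = 0
    for group, n in n_by_group.items():
        if n < 1:
            raise ValueError("each group needs at least one subject")
        means = targets_by_group[group]
        sds = spread_by_group.get(group, {})
        for k in range(n):
            counter += 1
            sid = f"{group}_{k:02d}"
            rng = substream(seed, sid, "targets")
            targets = {}
            for roi, mu in means.items():
                sd = sds.get(roi, 0.0)
                val = float(rng.normal(mu, sd)) if sd > 0 else float(mu)
                targets[roi] = max(val, 0.0)
            targets = _respect_whole_brain(targets)
            spec = replace(
                base_spec,
                target_fraction_by_roi=targets,
                seed=int(substream(seed, sid, "spec").integers(2**31 - 1)),
            )
            subjects.append(synthesize_subject(spec, age_group=group, subject_id=sid))
    return subjects


def _respect_whole_brain(targets: dict[str, float]) -> dict[str, float]:
    """Nudge a sampled target set so the whole-brain constraint stays feasible.

    With independent per-ROI draws the sub-ROI contribution can exceed the
    whole-brain draw; scale sub-ROI targets down just enough in that case.
    The feasibility bound used here is conservative (it assumes sub-ROIs
    could fill the brain) and only ever shrinks extreme draws.
    """
    if "whole_brain" not in targets:
        return targets
    wb = targets["whole_brain"]
    subs = {r: v for r, v in targets.items() if r != "whole_brain"}
    # sub-ROIs occupy well under a third of the brain in the schematic
    # anatomy; cap their weighted contribution at 90% of the whole-brain draw
    contribution = sum(subs.values()) / max(len(subs), 1) * 0.33
    if contribution > 0.9 * wb:
        factor = 0.9 * wb / contribution
        for r in subs:
            targets[r] = subs[r] * factor
    return targets
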