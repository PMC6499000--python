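"""Experiment manifest, fixture-study generation and pipeline orchestration.

The manifest maps image files to treatment labels and channel roles; the
pipeline executes the stages in dependency order (segment -> quantify ->
redox -> combination, with densitometry and cell-cycle profiling as
independent branches) and writes a per-spheroid CSV, JSON reports and a
machine-readable run log carrying the config hash and seed.  Outputs contain
no timestamps, so a rerun with the same manifest and seed is byte-identical.

``generate_fixtures`` builds a miniature three-model, multi-day, multi-dose
study (control / 2.5 J/cm2 PDT / 2, 10, 20 Gy RT / combinations on days 3, 5
and 12) from the phantom generators, with ground-truth sidecars.  The
designed effects follow the study's qualitative pattern: radiation stunts
growth in a dose- and time-dependent way (down to ~25% of control area for
20 Gy at day 12 in the most responsive model), photodynamic therapy drives
necrosis with little effect on size, the combination shrinks size slightly
sub-additively and boosts necrosis super-additively, and the glycolytic model
carries a positive ORR-necrosis coupling.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, Field, field_validator

from . import cellcycle as cc
from . import combination as comb
from . import densitometry as dens
from . import phantoms, quantify, redox
from .segment import SegmentationParams, segment_spheroid

__all__ = [
    "ChannelFiles",
    "ManifestEntry",
    "GelEntry",
    "DnaEntry",
    "ExperimentManifest",
    "FixtureConfig",
    "generate_fixtures",
    "run_pipeline",
    "PipelineRun",
]

ALL_STAGES = ("segment", "quantify", "redox", "combination", "blot", "cellcycle")


class ChannelFiles(BaseModel):
    """File paths per channel role; roles are unique by construction."""

    brightfield: str
    calcein: str | None = None
    pi: str | None = None
    nadh: str | None = None
    fad: str | None = None


class ManifestEntry(BaseModel):
    spheroid_id: str
    model: str
    day: int = Field(ge=0)
    pdt_fluence_J_cm2: float = Field(ge=0)
    rt_dose_Gy: float = Field(ge=0)
    pixel_size_um: float = Field(gt=0)
    channels: ChannelFiles


class GelEntry(BaseModel):
    blot_id: str
    image: str
    rois: str  # JSON list of {lane_id, protein, rect, placement}
    loading_protein: str = "beta_actin"
    reference_condition: str = "NT"


class DnaEntry(BaseModel):
    sample_id: str
    events_csv: str  # single column "dna_content"


class ExperimentManifest(BaseModel):
    entries: list[ManifestEntry] = Field(default_factory=list)
    gels: list[GelEntry] = Field(default_factory=list)
    dna_samples: list[DnaEntry] = Field(default_factory=list)
    segmentation: dict = Field(default_factory=dict)
    combination_alpha: float = 0.05

    @field_validator("entries")
    @classmethod
    def _non_empty(cls, v: list[ManifestEntry]) -> list[ManifestEntry]:
        if not v:
            raise ValueError("manifest contains no image entries")
        return v

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentManifest":
        path = Path(path)
        manifest = cls.model_validate_json(path.read_text())
        return manifest._resolved_against(path.parent)

    def _resolved_against(self, base: Path) -> "ExperimentManifest":
        m = self.model_copy(deep=True)
        for e in m.entries:
            for role, p in e.channels.model_dump().items():
                if p is not None:
                    setattr(e.channels, role, str((base / p).resolve()))
        for g in m.gels:
            g.image = str((base / g.image).resolve())
            g.rois = str((base / g.rois).resolve())
        for d in m.dna_samples:
            d.events_csv = str((base / d.events_csv).resolve())
        return m


# --------------------------------------------------------------------------
# Fixture study
# --------------------------------------------------------------------------

_DEFAULT_TREATMENTS = ((0.0, 0.0), (2.5, 0.0), (0.0, 2.0), (0.0, 10.0),
                       (2.5, 10.0), (0.0, 20.0), (2.5, 20.0))


class FixtureConfig(BaseModel):
    """Design of the miniature synthetic study."""

    seed: int = 0
    models: tuple[str, ...] = ("MIAPaCa2_pCAF", "Capan2_pCAF", "AsPC1_pCAF")
    days: tuple[int, ...] = (3, 5, 12)
    treatments: tuple[tuple[float, float], ...] = _DEFAULT_TREATMENTS  # (PDT J/cm2, RT Gy)
    replicates: int = Field(default=4, ge=1)
    frame: tuple[int, int] = (256, 256)
    pixel_size_um: float = Field(default=4.0, gt=0)
    noise_sd: float = Field(default=2.0, ge=0)
    with_redox: bool = True
    with_gels: bool = True
    with_dna: bool = True
    dna_events: int = Field(default=5000, ge=500)


# Designed treatment-response surface (per-model behaviour, see module docstring).
_MODEL_DESIGN = {
    "MIAPaCa2_pCAF": dict(radius=(150.0, 200.0, 280.0), rt_weight=(0.05, 0.35, 0.80),
                          pdt_necrosis=(0.10, 1.00, 0.60), halo=0, orr=0.25, orr_slope=0.5),
    "Capan2_pCAF": dict(radius=(120.0, 135.0, 145.0), rt_weight=(0.02, 0.06, 0.10),
                        pdt_necrosis=(1.00, 0.80, 0.30), halo=60, orr=0.45, orr_slope=0.0),
    "AsPC1_pCAF": dict(radius=(130.0, 145.0, 155.0), rt_weight=(0.02, 0.05, 0.10),
                       pdt_necrosis=(0.80, 0.40, 0.20), halo=40, orr=0.35, orr_slope=0.0),
}
_PDT_AREA_DEFICIT = 0.10
_PDT_NECROSIS_GAIN = 0.30
_RT_NECROSIS_GAIN = 0.02
_COMBO_AREA_SUBADDITIVITY = 0.8  # combined deficit = 0.8 x additive deficit
_COMBO_NECROSIS_SYNERGY = 0.12


def designed_effects(model: str, day_index: int, pdt: float, rt: float) -> tuple[float, float]:
    """(area factor vs control, necrotic fraction) designed for one group."""
    d = _MODEL_DESIGN[model]
    wd = d["rt_weight"][day_index]
    d_rt = wd * rt / 20.0
    d_pdt = _PDT_AREA_DEFICIT * wd * (pdt > 0)
    if pdt > 0 and rt > 0:
        deficit = _COMBO_AREA_SUBADDITIVITY * (d_rt + d_pdt)
    else:
        deficit = d_rt + d_pdt
    area_factor = max(1.0 - deficit, 0.05)

    wn = d["pdt_necrosis"][day_index]
    nf = 0.05 + _PDT_NECROSIS_GAIN * wn * (pdt > 0) + _RT_NECROSIS_GAIN * rt / 20.0
    if pdt > 0 and rt > 0:
        nf += _COMBO_NECROSIS_SYNERGY * wn
    return area_factor, float(np.clip(nf, 0.0, 1.0))


def _treatment_tag(pdt: float, rt: float) -> str:
    if pdt == 0 and rt == 0:
        return "NT"
    parts = []
    if pdt > 0:
        parts.append(f"PDT{pdt:g}")
    if rt > 0:
        parts.append(f"RT{rt:g}")
    return "+".join(parts)


def generate_fixtures(out_dir: str | Path, config: FixtureConfig | None = None) -> Path:
    """Write the fixture study (TIFFs, truth sidecars, manifest) to ``out_dir``.

    Returns the path of the manifest JSON.  The design table (one row per
    spheroid with its designed area factor and necrotic fraction) is written
    alongside as ``design.csv``; the seed only changes pixel noise and
    replicate jitter, never the design table's group structure.
    """
    config = config or FixtureConfig()
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    entries: list[dict] = []
    design_rows: list[dict] = []
    for model in config.models:
        d = _MODEL_DESIGN[model]
        for di, day in enumerate(config.days):
            for pdt, rt in config.treatments:
                area_factor, nf = designed_effects(model, di, pdt, rt)
                tag = _treatment_tag(pdt, rt)
                for rep in range(config.replicates):
                    sid = f"{model}_d{day}_{tag}_r{rep}"
                    radius = d["radius"][di] * np.sqrt(area_factor) * (1.0 + rng.normal(0.0, 0.04))
                    nf_i = float(np.clip(nf + rng.normal(0.0, 0.02), 0.0, 1.0))
                    halo_n = int(round(d["halo"] * (0.3 if di == 0 else 1.0)))
                    spec = phantoms.SpheroidPhantomSpec(
                        core_radius_um=float(max(radius, 20.0)),
                        halo_cell_count=halo_n,
                        necrotic_fraction=nf_i,
                        pixel_size_um=config.pixel_size_um,
                        noise_sd=config.noise_sd,
                        seed=int(rng.integers(0, 2**31 - 1)),
                        shape=config.frame,
                    )
                    img, truth = phantoms.make_spheroid_images(spec)
                    chan_paths: dict[str, str] = {}
                    for role in ("brightfield", "calcein", "pi"):
                        rel = f"images/{sid}_{role}.tif"
                        tifffile.imwrite(out / rel, img[role])
                        chan_paths[role] = rel
                    orr_mean = None
                    if config.with_redox:
                        orr_base = d["orr"] + d["orr_slope"] * (nf_i - 0.05)
                        field = np.clip(
                            orr_base + rng.normal(0.0, 0.01, size=config.frame), 0.0, 1.0
                        )
                        nadh, fad, orr_truth = phantoms.make_redox_pair(field, 200.0)
                        maskf = truth.total_mask.astype(float)
                        noise = rng.normal(0.0, config.noise_sd, size=(2,) + tuple(config.frame))
                        nadh = np.clip(nadh * maskf + noise[0], 0.0, None).astype(np.float32)
                        fad = np.clip(fad * maskf + noise[1], 0.0, None).astype(np.float32)
                        for role, arr in (("nadh", nadh), ("fad", fad)):
                            rel = f"images/{sid}_{role}.tif"
                            tifffile.imwrite(out / rel, arr)
                            chan_paths[role] = rel
                        orr_mean = float(orr_truth[truth.total_mask].mean())
                    sidecar = {
                        "core_area_um2": truth.core_area_um2,
                        "total_area_um2": truth.total_area_um2,
                        "necrotic_fraction": nf_i,
                        "pi_mean_in_mask": truth.per_channel_truth["pi_mean_in_mask"],
                        "designed_area_factor": area_factor,
                        "mean_orr": orr_mean,
                    }
                    (out / f"images/{sid}_truth.json").write_text(
                        json.dumps(sidecar, sort_keys=True, indent=1)
                    )
                    entries.append(
                        dict(spheroid_id=sid, model=model, day=day,
                             pdt_fluence_J_cm2=pdt, rt_dose_Gy=rt,
                             pixel_size_um=config.pixel_size_um, channels=chan_paths)
                    )
                    design_rows.append(
                        dict(spheroid_id=sid, model=model, day=day, treatment=tag,
                             pdt_fluence_J_cm2=pdt, rt_dose_Gy=rt,
                             designed_area_factor=area_factor,
                             designed_necrotic_fraction=nf_i)
                    )

    gels = []
    if config.with_gels:
        (out / "gels").mkdir(exist_ok=True)
        for model in config.models:
            lanes = []
            for pdt, rt in _DEFAULT_TREATMENTS:
                tag = _treatment_tag(pdt, rt)
                # Designed expression: PCNA flat-to-down with combo, gH2AX up with dose.
                pcna = 120.0 * (1.0 - 0.3 * (pdt > 0 and rt > 0) * rt / 20.0)
                gh2ax = 40.0 + 4.0 * rt / 2.0 + 25.0 * (pdt > 0)
                lanes.append((tag, {"PCNA": pcna, "gH2AX": min(gh2ax, 180.0),
                                    "beta_actin": 150.0}))
            gel_spec = phantoms.GelPhantomSpec(
                lanes=tuple(lanes), noise_sd=min(config.noise_sd, 2.0),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            gel_img, gel_truth, rois = phantoms.make_gel_image(gel_spec)
            tifffile.imwrite(out / f"gels/{model}.tif", gel_img)
            (out / f"gels/{model}_rois.json").write_text(json.dumps(rois, indent=1))
            (out / f"gels/{model}_truth.json").write_text(
                json.dumps(gel_truth, sort_keys=True, indent=1)
            )
            gels.append(dict(blot_id=model, image=f"gels/{model}.tif",
                             rois=f"gels/{model}_rois.json"))

    dna_samples = []
    if config.with_dna:
        (out / "dna").mkdir(exist_ok=True)
        subg1 = {"NT": 0.24, "PDT2.5": 0.314, "RT10": 0.309, "PDT2.5+RT10": 0.402}
        for model in config.models:
            for tag, f in subg1.items():
                rest = 1.0 - f
                spec = phantoms.DnaHistogramSpec(
                    n_events=config.dna_events,
                    fractions=(f, 0.55 * rest, 0.15 * rest, 0.30 * rest),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                events, labels = phantoms.make_dna_events(spec)
                sid = f"{model}_{tag}"
                pd.DataFrame({"dna_content": events}).to_csv(
                    out / f"dna/{sid}.csv", index=False
                )
                (out / f"dna/{sid}_truth.json").write_text(
                    json.dumps({"fractions": spec.fractions,
                                "label_fractions": np.bincount(labels, minlength=4)
                                .astype(float).__truediv__(len(labels)).tolist()},
                               indent=1)
                )
                dna_samples.append(dict(sample_id=sid, events_csv=f"dna/{sid}.csv"))

    manifest = dict(entries=entries, gels=gels, dna_samples=dna_samples,
                    segmentation={}, combination_alpha=0.05)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    pd.DataFrame(design_rows).to_csv(out / "design.csv", index=False)
    return manifest_path


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------


class PipelineRun:
    """Outcome of one pipeline execution."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.records: pd.DataFrame | None = None
        self.errors: dict[str, str] = {}
        self.reports: dict[str, object] = {}

    @property
    def ok(self) -> bool:
        return not self.errors


def _config_hash(manifest: ExperimentManifest, seed: int) -> str:
    payload = manifest.model_dump_json() + f"|seed={seed}"
    return hashlib.sha256(payload.encode()).hexdigest()


def _process_entry(entry: ManifestEntry, params: SegmentationParams) -> dict:
    chan = entry.channels
    bf = tifffile.imread(chan.brightfield)
    seg = segment_spheroid(bf, params, entry.pixel_size_um)
    row = dict(
        spheroid_id=entry.spheroid_id, model=entry.model, day=entry.day,
        pdt_fluence_J_cm2=entry.pdt_fluence_J_cm2, rt_dose_Gy=entry.rt_dose_Gy,
        detected=seg.detected, core_area_um2=seg.core_area_um2,
        total_area_um2=seg.total_area_um2, halo_area_um2=seg.halo_area_um2,
        mean_pi=np.nan, mean_calcein=np.nan, orr=np.nan,
    )
    if not seg.detected:
        return row
    for role, col in (("pi", "mean_pi"), ("calcein", "mean_calcein")):
        path = getattr(chan, role)
        if path:
            img = tifffile.imread(path)
            bg = quantify.background_level(img, seg.total_mask)
            row[col] = quantify.mean_intensity_in_mask(img, seg.total_mask, background=bg)
    if chan.nadh and chan.fad:
        orr_map = redox.compute_orr(tifffile.imread(chan.nadh), tifffile.imread(chan.fad),
                                    mask=seg.total_mask)
        row["orr"] = orr_map.spheroid_mean_orr
    return row


def _combination_report(records: pd.DataFrame, alpha: float) -> dict:
    """Effect vectors and additivity calls per (model, day) panel.

    Uses the highest PDT and RT doses present in the panel as the single
    agents and requires their combination group to exist.
    """
    report: dict = {}
    for (model, day), panel in records.groupby(["model", "day"]):
        pdt_doses = sorted(panel.loc[panel.pdt_fluence_J_cm2 > 0, "pdt_fluence_J_cm2"].unique())
        rt_doses = sorted(panel.loc[panel.rt_dose_Gy > 0, "rt_dose_Gy"].unique())
        if not pdt_doses or not rt_doses:
            continue
        pdt, rt = pdt_doses[-1], rt_doses[-1]

        def grp(p: float, r: float) -> comb.GroupSummary | None:
            sel = panel[(panel.pdt_fluence_J_cm2 == p) & (panel.rt_dose_Gy == r)].dropna(
                subset=["norm_area", "mean_pi"]
            )
            if sel.empty:
                return None
            return comb.summarize_group(model, int(day), p, r,
                                        sel.norm_area.to_numpy(), sel.mean_pi.to_numpy())

        groups = {"control": grp(0.0, 0.0), "pdt": grp(pdt, 0.0),
                  "rt": grp(0.0, rt), "combo": grp(pdt, rt)}
        if any(g is None for g in groups.values()):
            continue
        predicted = comb.predict_additive(groups["control"], groups["pdt"], groups["rt"])
        calls = comb.classify_additivity(groups["combo"], predicted, alpha=alpha)
        ev_p = comb.effect_vector(groups["pdt"], groups["control"])
        ev_r = comb.effect_vector(groups["rt"], groups["control"])
        report[f"{model}_day{day}"] = {
            "pdt_fluence_J_cm2": pdt, "rt_dose_Gy": rt,
            "effect_pdt": {"d_area": ev_p.d_area, "d_pi": ev_p.d_pi},
            "effect_rt": {"d_area": ev_r.d_area, "d_pi": ev_r.d_pi},
            "predicted": {"area": predicted.area, "pi": predicted.pi,
                          "sigma_area": predicted.sigma_area, "sigma_pi": predicted.sigma_pi},
            "calls": {axis: call.to_dict() for axis, call in calls.items()},
        }
    return report


def run_pipeline(
    manifest: ExperimentManifest | str | Path,
    out_dir: str | Path,
    stages: tuple[str, ...] = ALL_STAGES,
    seed: int = 0,
) -> PipelineRun:
    """Execute the requested stages over a manifest and write the run directory.

    Failures are recorded per entry and do not abort the remaining entries;
    inspect ``PipelineRun.ok`` / ``.errors`` (the CLI exits non-zero on any
    failure).
    """
    if not isinstance(manifest, ExperimentManifest):
        manifest = ExperimentManifest.load(manifest)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run = PipelineRun(out)
    params = SegmentationParams(**manifest.segmentation)

    image_stages = {"segment", "quantify", "redox", "combination"} & set(stages)
    if image_stages:
        rows = []
        for entry in manifest.entries:
            try:
                rows.append(_process_entry(entry, params))
            except Exception as exc:  # noqa: BLE001 - per-entry isolation
                run.errors[entry.spheroid_id] = f"{type(exc).__name__}: {exc}"
        records = pd.DataFrame(rows).sort_values("spheroid_id", ignore_index=True)
        if {"quantify", "combination"} & set(stages) and not records.empty:
            try:
                records = quantify.normalize_areas(records[records.detected].copy())
            except ValueError as exc:
                run.errors["normalize_areas"] = str(exc)
        run.records = records
        records.to_csv(out / "spheroids.csv", index=False)

        if "quantify" in stages and "norm_area" in records.columns:
            stats_report = {}
            for (model, day), panel in records.groupby(["model", "day"]):
                for readout in ("norm_area", "mean_pi"):
                    groups = {
                        _treatment_tag(p, r): g[readout].dropna().to_numpy()
                        for (p, r), g in panel.groupby(["pdt_fluence_J_cm2", "rt_dose_Gy"])
                    }
                    rep = quantify.compare_groups(groups)
                    stats_report[f"{model}_day{day}_{readout}"] = {
                        "test": rep.test, "statistic": rep.statistic, "p_value": rep.p_value,
                        "pairwise": rep.pairwise, "excluded": rep.excluded,
                    }
            run.reports["group_stats"] = stats_report
            (out / "group_stats.json").write_text(
                json.dumps(stats_report, sort_keys=True, indent=1, default=float)
            )

        if "combination" in stages and "norm_area" in records.columns:
            report = _combination_report(records[records.detected], manifest.combination_alpha)
            run.reports["combination"] = report
            (out / "combination.json").write_text(
                json.dumps(report, sort_keys=True, indent=1, default=float)
            )

    if "blot" in stages and manifest.gels:
        blot_rows = []
        for gel in manifest.gels:
            try:
                img = tifffile.imread(gel.image)
                rois = [dens.BandRoi(r["lane_id"], r["protein"], tuple(r["rect"]),
                                     r.get("placement", "above"))
                        for r in json.loads(Path(gel.rois).read_text())]
                quants = [dens.quantify_band(img, roi, other_bands=rois) for roi in rois]
                quants = dens.normalize_expression(
                    quants, gel.loading_protein, gel.reference_condition
                )
                for q in quants:
                    blot_rows.append(dict(blot_id=gel.blot_id, lane_id=q.lane_id,
                                          protein=q.protein, raw_mean=q.raw_mean,
                                          background_mean=q.background_mean, signal=q.signal,
                                          normalized_expression=q.normalized_expression,
                                          flagged=q.flagged))
            except Exception as exc:  # noqa: BLE001
                run.errors[f"blot:{gel.blot_id}"] = f"{type(exc).__name__}: {exc}"
        if blot_rows:
            pd.DataFrame(blot_rows).to_csv(out / "blots.csv", index=False)

    if "cellcycle" in stages and manifest.dna_samples:
        cc_report = {}
        for sample in manifest.dna_samples:
            try:
                events = pd.read_csv(sample.events_csv)["dna_content"].to_numpy()
                profile = cc.fit_cell_cycle(events)
                cc_report[sample.sample_id] = {
                    "f_subg1": profile.f_subg1, "f_g1": profile.f_g1,
                    "f_s": profile.f_s, "f_g2m": profile.f_g2m,
                    "g1_mean": profile.g1_mean, "g2m_mean": profile.g2m_mean,
                    "n_events": profile.n_events, "ok": profile.ok,
                    "message": profile.message,
                }
            except Exception as exc:  # noqa: BLE001
                run.errors[f"cellcycle:{sample.sample_id}"] = f"{type(exc).__name__}: {exc}"
        run.reports["cellcycle"] = cc_report
        (out / "cellcycle.json").write_text(
            json.dumps(cc_report, sort_keys=True, indent=1, default=float)
        )

    log = {
        "config_hash": _config_hash(manifest, seed),
        "seed": seed,
        "stages": list(stages),
        "n_entries": len(manifest.entries),
        "n_failed": len(run.errors),
        "errors": run.errors,
    }
    (out / "run_log.json").write_text(json.dumps(log, sort_keys=True, indent=1))
    return run
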