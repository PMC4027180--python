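"""End-to-end orchestration of all analysis stages from a config file.

A :class:`PipelineConfig` names the input files per stage plus the physical
parameters (field, temperature, viscosity) that the relaxation stage needs;
``run`` executes every enabled stage in dependency order, isolating failures
so one broken stage does not abort the rest, and returns a JSON-serializable
report.  ``demo`` generates a full synthetic bundle and analyzes it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__, csi, csp, itcseq, motifs, relaxhydro, structqc, \
    synthdata, titrate

STAGES = ("motifs", "csi", "csp", "relax", "itc", "titrate", "structqc")


@dataclass
class PipelineConfig:
    """Paths and parameters for a pipeline run.

    Physical parameters have no hidden defaults: the relaxation stage
    requires explicit field/temperature/viscosity values in the config.
    """

    outdir: str
    seed: int = 0
    # inputs (any may be None to disable the stage needing it)
    promoter_fasta: Optional[str] = None
    tss_offset: Optional[int] = None
    shifts_csv: Optional[str] = None
    hsqc_free_csv: Optional[str] = None
    hsqc_bound_csv: Optional[str] = None
    relax_r1_csv: Optional[str] = None
    relax_r2_csv: Optional[str] = None
    itc_csv: Optional[str] = None
    itc_design_json: Optional[str] = None
    titration_csv: Optional[str] = None
    melt_free_csv: Optional[str] = None
    melt_bound_csv: Optional[str] = None
    emsa_csv: Optional[str] = None
    emission_free_csv: Optional[str] = None
    emission_bound_csv: Optional[str] = None
    ensemble_pdb: Optional[str] = None
    # physical parameters (explicit, no hidden defaults)
    field_1h_mhz: Optional[float] = None
    temperature_k: Optional[float] = None
    viscosity_pa_s: Optional[float] = None
    enabled: tuple = STAGES

    def validate(self) -> None:
        problems = []
        inputs = {
            "promoter_fasta": self.promoter_fasta,
            "shifts_csv": self.shifts_csv,
            "hsqc_free_csv": self.hsqc_free_csv,
            "hsqc_bound_csv": self.hsqc_bound_csv,
            "relax_r1_csv": self.relax_r1_csv,
            "relax_r2_csv": self.relax_r2_csv,
            "itc_csv": self.itc_csv, "itc_design_json": self.itc_design_json,
            "titration_csv": self.titration_csv,
            "melt_free_csv": self.melt_free_csv,
            "melt_bound_csv": self.melt_bound_csv,
            "emsa_csv": self.emsa_csv, "ensemble_pdb": self.ensemble_pdb,
            "emission_free_csv": self.emission_free_csv,
            "emission_bound_csv": self.emission_bound_csv,
        }
        for name, path in inputs.items():
            if path is not None and not Path(path).exists():
                problems.append(f"{name}: file not found: {path}")
        for stage in self.enabled:
            if stage not in STAGES:
                problems.append(f"unknown stage {stage!r}")
        if "relax" in self.enabled and self.relax_r1_csv is not None:
            for p in ("field_1h_mhz", "temperature_k", "viscosity_pa_s"):
                v = getattr(self, p)
                if v is None or v <= 0:
                    problems.append(f"relax stage requires positive {p}")
        if problems:
            raise ValueError("invalid config:\n  " + "\n  ".join(problems))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True,
            default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _read_fasta(path) -> tuple[str, str]:
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.description, str(rec.seq).upper()


def _stage_motifs(cfg: PipelineConfig) -> dict:
    desc, bases = _read_fasta(cfg.promoter_fasta)
    tss = cfg.tss_offset
    if tss is None and "tss_offset=" in desc:
        tss = int(desc.split("tss_offset=")[1].split()[0])
    seq = motifs.DnaSequence(name=desc.split()[0], bases=bases,
                             tss_offset=tss)
    hits = motifs.scan_motif(seq)
    pairs = motifs.find_paired_sites(seq)
    return {
        "n_hits": len(hits),
        "n_paired_sites": len(pairs),
        "paired_sites": [
            {"start": p.first.start, "end": p.second.end, "span": p.span,
             "spacer": p.spacer, "center_distance": p.center_distance,
             "tss_span": [seq.tss_position(p.first.start),
                          seq.tss_position(p.second.end)]
             if tss is not None else None}
            for p in pairs],
    }


def _stage_csi(cfg: PipelineConfig) -> dict:
    shifts = pd.read_csv(cfg.shifts_csv)
    ss = csi.analyze_shifts(shifts)
    return {"topology": ss.topology, "n_helices": ss.n_helices,
            "n_strands": ss.n_strands,
            "segments": [list(s) for s in ss.segments]}


def _stage_csp(cfg: PipelineConfig) -> dict:
    free = pd.read_csv(cfg.hsqc_free_csv)
    bound = pd.read_csv(cfg.hsqc_bound_csv)
    cls = csp.analyze_pair(free, bound)
    return {"interface": sorted(cls.interface),
            "csp_mean": cls.csp_mean, "csp_sd": cls.csp_sd,
            "n_lost_peaks": len(cls.lost)}


def _stage_relax(cfg: PipelineConfig) -> dict:
    r1 = relaxhydro.RelaxationSeries("R1", cfg.field_1h_mhz,
                                     pd.read_csv(cfg.relax_r1_csv))
    r2 = relaxhydro.RelaxationSeries("R2", cfg.field_1h_mhz,
                                     pd.read_csv(cfg.relax_r2_csv))
    rates, est = relaxhydro.analyze_relaxation(
        r1, r2, temperature_k=cfg.temperature_k,
        viscosity_pa_s=cfg.viscosity_pa_s)
    return {"tau_c_ns": est.tau_c_ns, "tau_c_sd_ns": est.tau_c_sd_ns,
            "n_residues": est.n_residues, "r_h_nm": est.r_h_nm,
            "n_pass_coarse": int(rates["pass_coarse"].sum()),
            "n_pass_fine": int(rates["pass_fine"].sum())}


def _stage_itc(cfg: PipelineConfig) -> dict:
    table = pd.read_csv(cfg.itc_csv)
    design = json.loads(Path(cfg.itc_design_json).read_text())
    tg = itcseq.Thermogram(
        cell_volume_l=design["cell_volume_l"],
        cell_conc_m=design["cell_conc_m"],
        syringe_conc_m=design["syringe_conc_m"],
        injection_volumes_l=table["inj_vol_ul"].to_numpy() * 1e-6,
        heats_cal=table["heat_ucal"].to_numpy() * 1e-6,
        temperature_k=design.get("temperature_k", 295.15))
    res = itcseq.SequentialBindingModel(tg).fit(seed=cfg.seed)
    return {"kd1_nm": res.kd1_nm, "kd2_um": res.kd2_um,
            "dh1_kcal": res.params.dh1, "dh2_kcal": res.params.dh2,
            "thermodynamics": res.thermodynamics()}


def _stage_titrate(cfg: PipelineConfig) -> dict:
    out: dict = {}
    if cfg.titration_csv:
        t = pd.read_csv(cfg.titration_csv)
        br = titrate.breakpoint_stoichiometry(t["ratio"], t["signal"])
        out["breakpoint_ratio"] = br.breakpoint
    if cfg.melt_free_csv and cfg.melt_bound_csv:
        mf = pd.read_csv(cfg.melt_free_csv)
        mb = pd.read_csv(cfg.melt_bound_csv)
        out["tm_free_c"] = titrate.tm_from_melt(mf["temperature_c"], mf["a260"])
        out["tm_bound_c"] = titrate.tm_from_melt(mb["temperature_c"], mb["a260"])
        out["delta_tm_c"] = out["tm_bound_c"] - out["tm_free_c"]
    if cfg.emsa_csv:
        e = pd.read_csv(cfg.emsa_csv)
        hill = titrate.hill_fit(e["conc_um"], e["fraction_bound"])
        out["hill_n"] = hill.n
        out["hill_k_half_um"] = hill.k_half
    if cfg.emission_free_csv and cfg.emission_bound_csv:
        ef = pd.read_csv(cfg.emission_free_csv)
        eb = pd.read_csv(cfg.emission_bound_csv)
        out["lambda_max_free_nm"] = titrate.lambda_max(
            ef["wavelength_nm"], ef["intensity"])
        out["lambda_max_bound_nm"] = titrate.lambda_max(
            eb["wavelength_nm"], eb["intensity"])
        out["blue_shift_nm"] = out["lambda_max_free_nm"] - \
            out["lambda_max_bound_nm"]
    return out


def _stage_structqc(cfg: PipelineConfig) -> dict:
    ens = structqc.read_pdb_ensemble(cfg.ensemble_pdb)
    bb = structqc.ensemble_rmsd(ens, atoms="backbone")
    heavy = structqc.ensemble_rmsd(ens, atoms="heavy")
    return {"n_models": len(ens), "backbone_rmsd_a": bb.mean_rmsd,
            "heavy_rmsd_a": heavy.mean_rmsd}


_STAGE_FUNCS = {
    "motifs": (_stage_motifs, ("promoter_fasta",)),
    "csi": (_stage_csi, ("shifts_csv",)),
    "csp": (_stage_csp, ("hsqc_free_csv", "hsqc_bound_csv")),
    "relax": (_stage_relax, ("relax_r1_csv", "relax_r2_csv")),
    "itc": (_stage_itc, ("itc_csv", "itc_design_json")),
    "titrate": (_stage_titrate, ("titration_csv", "melt_free_csv",
                                 "emsa_csv")),
    "structqc": (_stage_structqc, ("ensemble_pdb",)),
}


def run(cfg: PipelineConfig) -> dict:
    """Execute all enabled stages; failures are recorded, not propagated."""
    cfg.validate()
    report: dict = {
        "provenance": {"package": "wingbind", "version": __version__,
                       "config_digest": cfg.digest(), "seed": cfg.seed},
        "stages": {},
    }
    for stage in cfg.enabled:
        func, needs = _STAGE_FUNCS[stage]
        if all(getattr(cfg, n) is None for n in needs):
            continue   # stage has no inputs; treat as disabled
        try:
            report["stages"][stage] = {"status": "ok", "result": func(cfg)}
        except Exception as exc:   # noqa: BLE001 - stage isolation
            report["stages"][stage] = {"status": "error",
                                       "error": f"{type(exc).__name__}: {exc}"}
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=float))
    return report


def demo(seed: int = 7, outdir: str = "wingbind_demo") -> dict:
    """Generate the full synthetic bundle and analyze every stage of it."""
    outdir = Path(outdir)
    datadir = outdir / "data"
    spec = synthdata.SynthSpec(seed=seed)
    synthdata.write_bundle(spec, datadir)
    cfg = PipelineConfig(
        outdir=str(outdir), seed=seed,
        promoter_fasta=str(datadir / "promoter.fasta"),
        shifts_csv=str(datadir / "shifts.csv"),
        hsqc_free_csv=str(datadir / "hsqc_free.csv"),
        hsqc_bound_csv=str(datadir / "hsqc_bound.csv"),
        relax_r1_csv=str(datadir / "relax_r1.csv"),
        relax_r2_csv=str(datadir / "relax_r2.csv"),
        itc_csv=str(datadir / "itc.csv"),
        itc_design_json=str(datadir / "itc_design.json"),
        titration_csv=str(datadir / "titration.csv"),
        melt_free_csv=str(datadir / "melt_free.csv"),
        melt_bound_csv=str(datadir / "melt_bound.csv"),
        emsa_csv=str(datadir / "emsa.csv"),
        emission_free_csv=str(datadir / "emission_free.csv"),
        emission_bound_csv=str(datadir / "emission_bound.csv"),
        field_1h_mhz=spec.field_1h_mhz,
        temperature_k=298.15,
        viscosity_pa_s=relaxhydro.WATER_VISCOSITY_25C,
    )
    return run(cfg)
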