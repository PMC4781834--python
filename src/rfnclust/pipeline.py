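"""End-to-end orchestration: config, deterministic seeding, the full chain.

simulate/load -> (optional) preprocess -> connectivity -> dendrogram ->
iterative RFN extraction -> FWER curve -> per-RFN dissection -> reports.

Every artifact is a plain-text table or node list plus a provenance sidecar;
re-running with an identical config and seed reproduces byte-identical text
outputs (the clustering chain itself is fully deterministic — all randomness
lives in the synthetic data draw and the FWER Monte Carlo, both seeded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import dissect as dis
from . import preprocess as prep
from . import report as rep
from . import stats as sig
from . import synthetic as syn
from .tree import average_linkage, write_node_list

__all__ = ["PipelineConfig", "PipelineResult", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat configuration of the whole pipeline (file format: key = value)."""

    seed: int = 0
    out_dir: str = "results"

    # connectivity / clustering
    tau: float = 0.3
    d_max: float = 9.0
    k_initial: int = 64
    s_min: int = 50
    s_max: int = 5000
    ic_depth: int = 2
    dissect_k_max: int = 80

    # significance
    alpha_fwer: float = 0.01
    size_floor: int = 12
    n_iterations: int = 10_000
    connectivity_rule: str = "faces"
    fwhm_mm: float | None = None  # None: estimate from the data
    cc_grid_start: float = 0.05
    cc_grid_stop: float = 0.9
    cc_grid_step: float = 0.05

    # optional preprocessing (off by default for the bundled synthetic demo,
    # whose planted signal is already band-limited)
    detrend_order: int | None = None
    lowpass_hz: float | None = None
    smooth_fwhm_mm: float = 0.0

    # bundled synthetic demo (used when no input volumes are given)
    grid_shape: tuple[int, int, int] = (12, 10, 5)
    network_sub_sizes: tuple[tuple[int, ...], ...] = ((80, 80, 80), (100, 100))
    cc_within_sub: float = 0.6
    cc_within_net: float = 0.4
    cc_between_net: float = 0.05
    n_subjects: int = 20
    n_timepoints: int = 290

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {json.dumps(getattr(self, f.name))}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kwargs = {}
        names = {f.name: f for f in dataclasses.fields(cls)}
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {ln}: expected 'key = value'")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in names:
                raise ValueError(f"line {ln}: unknown key {key!r}")
            kwargs[key] = json.loads(value.strip())
        cfg = cls(**kwargs)
        # JSON round-trips tuples as lists; normalize
        cfg.grid_shape = tuple(cfg.grid_shape)
        cfg.network_sub_sizes = tuple(tuple(s) for s in cfg.network_sub_sizes)
        return cfg

    def digest(self) -> str:
        payload = json.dumps(
            {f.name: getattr(self, f.name) for f in dataclasses.fields(self)},
            sort_keys=True,
            default=list,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Return a list of violations (empty iff the config is valid)."""
    v: list[str] = []
    if not 0 <= cfg.tau < 1:
        v.append("tau: must lie in [0, 1)")
    if not cfg.d_max > 2:
        v.append("d_max: must exceed 2")
    if cfg.k_initial < 2:
        v.append("k_initial: must be >= 2")
    if not 0 < cfg.s_min < cfg.s_max:
        v.append("s_min/s_max: need 0 < s_min < s_max")
    if not 0 < cfg.alpha_fwer < 1:
        v.append("alpha_fwer: must lie in (0, 1)")
    if cfg.size_floor < 1:
        v.append("size_floor: must be >= 1")
    if cfg.n_iterations < 1:
        v.append("n_iterations: must be >= 1")
    if cfg.ic_depth < 1:
        v.append("ic_depth: must be >= 1")
    if cfg.dissect_k_max < 2:
        v.append("dissect_k_max: must be >= 2")
    if cfg.connectivity_rule not in ("faces", "faces+edges", "faces+edges+corners"):
        v.append("connectivity_rule: unknown rule")
    if cfg.n_timepoints < 10:
        v.append("n_timepoints: must be >= 10")
    if cfg.smooth_fwhm_mm < 0:
        v.append("smooth_fwhm_mm: must be non-negative")
    if not (0 <= cfg.cc_between_net < cfg.cc_within_net < cfg.cc_within_sub < 1):
        v.append("cc targets: need 0 <= between_net < within_net < within_sub < 1")
    return v


@dataclass
class PipelineResult:
    out_dir: Path
    mask: object
    ground_truth: object
    mean_cc: object
    dendrogram: object
    candidates: list
    fwer_curve: object
    subnetworks: dict = field(default_factory=dict)  # rfn cluster_id -> SubDendrogram
    dissociable: dict = field(default_factory=dict)
    k_star: int | None = None
    ic_star: float | None = None


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig, volumes=None, mask=None) -> PipelineResult:
    """Execute the full chain and write all artifacts under ``cfg.out_dir``.

    With no ``volumes``, the bundled synthetic demo spec is simulated from
    ``cfg.seed``.  Any stage error aborts with the stage name; artifacts
    written so far are retained.
    """
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ground_truth = None

    try:
        stage = "simulate"
        if volumes is None:
            spec = syn.nested_block_spec(
                cfg.grid_shape,
                [list(s) for s in cfg.network_sub_sizes],
                cc_within_sub=cfg.cc_within_sub,
                cc_within_net=cfg.cc_within_net,
                cc_between_net=cfg.cc_between_net,
                n_subjects=cfg.n_subjects,
                n_timepoints=cfg.n_timepoints,
                seed=cfg.seed,
                smooth_fwhm_mm=cfg.smooth_fwhm_mm,
            )
            volumes, mask, ground_truth = syn.generate_dataset(spec)
            syn.write_ground_truth(ground_truth, mask, out)
        elif mask is None:
            raise ValueError("mask is required when volumes are provided")

        stage = "preprocess"
        if cfg.detrend_order is not None:
            volumes = [prep.detrend_poly(v, cfg.detrend_order) for v in volumes]
        if cfg.lowpass_hz is not None:
            volumes = [prep.lowpass(v, cfg.lowpass_hz) for v in volumes]
        fwhm = cfg.fwhm_mm
        if fwhm is None:
            est = prep.estimate_fwhm(volumes[0], mask)
            fwhm = est.geometric_mean_mm

        stage = "connectivity"
        ccs = [conn.threshold_cc(conn.subject_cc(v, mask), cfg.tau) for v in volumes]
        mcc = conn.group_average(ccs, keep_stack=True)
        dist = conn.to_distance(mcc, cfg.d_max)
        conn.save_condensed(out / "mean_cc.npy", mcc, mask)
        hist = conn.cc_histogram(mcc)
        pd.DataFrame(hist, columns=["bin_low", "count"]).to_csv(
            out / "mean_cc_histogram.tsv", sep="\t", index=False
        )

        stage = "cluster"
        dend = average_linkage(dist)
        (out / "tree.txt").write_text(write_node_list(dend))

        stage = "extract"
        xcfg = dis.ExtractionConfig(k_initial=cfg.k_initial, s_min=cfg.s_min, s_max=cfg.s_max)
        candidates, log = dis.extract_rfns(dend, xcfg)
        pd.DataFrame(
            [
                {
                    "iteration": r.iteration,
                    "parent_node": r.parent_node,
                    "k_used": r.k_used,
                    "node_id": r.node_id,
                    "size": r.size,
                    "status": r.status,
                }
                for r in log
            ]
        ).to_csv(out / "extraction_log.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"cluster_id": c.cluster_id, "node_id": c.node_id, "size": c.size}
                for c in candidates
            ]
        ).to_csv(out / "rfn_candidates.tsv", sep="\t", index=False)

        stage = "fwer"
        scfg = sig.SignificanceConfig(
            alpha_fwer=cfg.alpha_fwer,
            size_floor=cfg.size_floor,
            n_iterations=cfg.n_iterations,
            connectivity_rule=cfg.connectivity_rule,
            seed=cfg.seed,
        )
        nz = mcc.values > 0
        cc_grid = np.arange(cfg.cc_grid_start, cfg.cc_grid_stop + 1e-9, cfg.cc_grid_step)
        if mcc.stack is not None and np.count_nonzero(nz) >= 10:
            t_all, _ = sig.pair_t_test(mcc.stack[:, nz])
            finite = np.isfinite(t_all)
            env = sig.lower_envelope(
                t_all[finite], mcc.values[nz][finite].astype(np.float64), 0.01, df=mcc.n_subjects - 1
            )
        else:
            env = sig.analytic_envelope(cfg.tau, cfg.n_timepoints, mcc.n_subjects, cc_grid)
        curve = sig.fwer_curve(mask, env, fwhm, scfg, cc_grid)
        pd.DataFrame({"min_cc": curve.min_cc, "s_min": curve.s_min}).to_csv(
            out / "fwer_curve.tsv", sep="\t", index=False
        )

        stage = "dissect"

        def min_cc_of(leaves: np.ndarray) -> float:
            if len(leaves) < 2:
                return float("nan")
            return rep.cluster_summary(leaves, mcc)[0]

        def predicate(size: int, min_cc: float) -> bool:
            return sig.is_significant((size, min_cc), curve, scfg)

        # IC-curve cut selection between the two largest candidate RFNs
        k_star = ic_star = None
        big = sorted(candidates, key=lambda c: -c.size)[:2]
        curves = []
        for c in big:
            n_sub = c.size
            if n_sub >= 3:
                km = min(cfg.dissect_k_max, n_sub)
                curves.append(dis.ic_curve(dend, c.node_id, km, depth=cfg.ic_depth))
        if len(curves) == 2:
            hit = dis.ic_intersection(curves[0], curves[1])
            if hit is not None:
                k_star, ic_star = hit

        result = PipelineResult(
            out_dir=out,
            mask=mask,
            ground_truth=ground_truth,
            mean_cc=mcc,
            dendrogram=dend,
            candidates=candidates,
            fwer_curve=curve,
            k_star=k_star,
            ic_star=ic_star,
        )

        stage = "report"
        k_cut = k_star if k_star is not None else cfg.dissect_k_max
        for c in candidates:
            diss, terminal = dis.dissect_significant(
                dend, c.node_id, predicate, min_cc_of, k_max=min(k_cut, c.size)
            )
            result.dissociable[c.cluster_id] = diss
            pd.DataFrame(
                [{"node_id": nd, "left": l, "right": r} for nd, l, r in diss]
            ).to_csv(out / f"rfn{c.cluster_id}_dissociable.tsv", sep="\t", index=False)
            if len(terminal) >= 2:
                sub = rep.build_subdendrogram(dend, terminal)
                rows = rep.make_report_rows(dend, sub, mcc, mask, ic_depth=cfg.ic_depth)
                rep.write_reports(sub, rows, mask, out, prefix=f"rfn{c.cluster_id}_subnetworks")
                result.subnetworks[c.cluster_id] = sub

        provenance = {
            "config_digest": cfg.digest(),
            "seed": cfg.seed,
            "mask_hash": mask.ordering_hash(),
            "fwhm_mm_used": float(fwhm),
            "n_candidates": len(candidates),
            "k_star": k_star,
            "ic_star": ic_star,
        }
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=1, sort_keys=True)
        cfg.to_file(out / "config.txt")
        return result
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
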