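"""End-to-end orchestration: dataset directory -> results directory.

Consumes the on-disk layout written by :func:`fnirspeech.simulate.simulate_group`
(or equivalently formatted real data): a ``participants.tsv`` table, a
montage YAML, and per-participant raw HDF5 blocks with events and
transcript TSVs. Produces per-contrast activation CSVs, functional-
connectivity contrast matrices (CSV + heatmap), per-participant QC JSON,
and a markdown report.

Per-participant results are cached under ``<out>/cache`` keyed by a
content hash of the participant's inputs and the configuration, so
unchanged reruns are cheap.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .activation import ActivationBetas, activation_contrasts, glm_betas
from .connectivity import (
    FC_CONTRASTS,
    ConnectivityMatrix,
    average_blocks,
    condition_fc,
    contrast_to_csv,
    paired_contrast,
    render_contrast,
)
from .io import read_events, read_raw, write_json
from .montage import ChannelMap, paper_montage, read_montage_yaml, region_ordered_ids
from .preprocess import PreprocessConfig, preprocess_recording
from .segmentation import build_condition_timeline

log = logging.getLogger("fnirspeech")

__all__ = ["PipelineConfig", "run_pipeline", "report"]

CONDITIONS_FC = ("rest", "private", "inner", "outer")


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    fdr_q: float = 0.05
    fc_alpha: float = 0.005
    min_segment_s: float = 1.0
    min_fc_samples: int = 30
    make_figures: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("fdr_q", "fc_alpha", "min_segment_s", "min_fc_samples", "seed",
                    "make_figures"):
            if key in doc:
                setattr(cfg, key, doc[key])
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["preprocess"]["manual_exclusions"] = sorted(
            self.preprocess.manual_exclusions
        )
        return d


def _content_hash(paths: list[Path], cfg: PipelineConfig) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    h.update(json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode())
    return h.hexdigest()


def _process_participant(
    pdir: Path, cmap: ChannelMap, cfg: PipelineConfig
) -> tuple[np.ndarray, dict[str, ConnectivityMatrix], dict]:
    """One participant: preprocess both blocks, fit per-block GLMs and FC,
    average across blocks. Returns (betas [C x 3], fc-by-condition, qc)."""
    events = read_events(pdir / "events.tsv")
    betas_blocks = []
    fc_blocks: dict[str, list[ConnectivityMatrix]] = {c: [] for c in CONDITIONS_FC}
    qc_info: dict = {}
    valid = set(cmap.valid_ids)
    for ev in events:
        rec = read_raw(pdir / f"block-{ev.block_id}_raw.h5")
        hb, qc = preprocess_recording(rec, cfg.preprocess)
        qc_info[f"block-{ev.block_id}"] = qc.to_dict()
        usable = valid - qc.excluded_channels
        mask = np.array([cid in usable for cid in rec.channel_ids])
        timeline = build_condition_timeline(
            ev, rec.fs, rec.duration_s, min_segment_s=cfg.min_segment_s
        )
        beta, _, _ = glm_betas(
            hb, timeline, cfg.preprocess.filters.hrf_params,
            filter_like=cfg.preprocess, channel_mask=mask,
        )
        betas_blocks.append(beta)
        for cond in CONDITIONS_FC:
            try:
                fc = condition_fc(
                    hb, timeline, cond, cmap,
                    min_segment_s=cfg.min_segment_s,
                    min_samples=cfg.min_fc_samples,
                    channel_mask=mask,
                )
            except ValueError:
                continue
            fc_blocks[cond].append(fc)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # montage-excluded channels are all-NaN across blocks by design
        _warnings.filterwarnings("ignore", message="Mean of empty slice")
        betas = np.nanmean(np.stack(betas_blocks), axis=0)
    fc_avg: dict[str, ConnectivityMatrix] = {}
    for cond, mats in fc_blocks.items():
        if not mats:
            continue
        fc_avg[cond] = average_blocks(mats[0], mats[1] if len(mats) > 1 else None)
    return betas, fc_avg, qc_info


def run_pipeline(dataset_dir, out_dir, cfg: PipelineConfig | None = None) -> Path:
    """Run preprocess -> segmentation -> activation -> connectivity -> report.

    Returns the results directory. Stage timings and QC summaries are
    logged; any stage failure raises with the participant and file named.
    """
    cfg = cfg or PipelineConfig()
    dataset_dir, out_dir = Path(dataset_dir), Path(out_dir)
    if not (dataset_dir / "participants.tsv").exists():
        raise FileNotFoundError(f"no participants.tsv in {dataset_dir}")
    table = pd.read_csv(dataset_dir / "participants.tsv", sep="\t")
    montage_path = dataset_dir / "montage.yaml"
    cmap = read_montage_yaml(montage_path) if montage_path.exists() else paper_montage()
    ordered_ids = region_ordered_ids(cmap)

    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "cache").mkdir(exist_ok=True)
    (out_dir / "qc").mkdir(exist_ok=True)

    all_betas, fc_by_pid = [], {}
    n_channels = None
    for _, row in table.iterrows():
        pid = str(row["participant_id"])
        pdir = dataset_dir / pid
        t0 = time.time()
        inputs = sorted(pdir.glob("*_raw.h5")) + [pdir / "events.tsv"]
        key = _content_hash(inputs, cfg)
        cache = out_dir / "cache" / f"{pid}.npz"
        qc_path = out_dir / "qc" / f"{pid}.json"
        if cache.exists():
            arch = np.load(cache, allow_pickle=False)
            if str(arch["hash"]) == key:
                betas = arch["betas"]
                fc_avg = {
                    cond: ConnectivityMatrix(
                        z=arch[f"fc_{cond}"], condition=cond, participant_id=pid,
                        channel_ids=ordered_ids,
                        n_samples_used=int(arch[f"fc_n_{cond}"]),
                        n_blocks=int(arch[f"fc_b_{cond}"]),
                    )
                    for cond in CONDITIONS_FC
                    if f"fc_{cond}" in arch
                }
                all_betas.append(betas)
                fc_by_pid[pid] = fc_avg
                n_channels = betas.shape[0]
                log.info("%s: cached", pid)
                continue
        try:
            betas, fc_avg, qc_info = _process_participant(pdir, cmap, cfg)
        except Exception as err:
            raise RuntimeError(f"stage 'participant' failed for {pid}: {err}") from err
        write_json(qc_info, qc_path)
        payload = {"hash": key, "betas": betas}
        for cond, m in fc_avg.items():
            payload[f"fc_{cond}"] = m.z
            payload[f"fc_n_{cond}"] = m.n_samples_used
            payload[f"fc_b_{cond}"] = m.n_blocks
        np.savez(cache, **payload)
        all_betas.append(betas)
        fc_by_pid[pid] = fc_avg
        n_channels = betas.shape[0]
        log.info("%s: processed in %.1f s", pid, time.time() - t0)

    groups = table["group"].astype(str).tolist()
    pids = table["participant_id"].astype(str).tolist()
    betas_obj = ActivationBetas(
        beta=np.stack(all_betas),
        residual_variance=np.full((len(all_betas), n_channels), np.nan),
        channel_ids=list(range(1, n_channels + 1)),
        participant_ids=pids,
    )
    act = activation_contrasts(betas_obj, groups, q=cfg.fdr_q)
    act_dir = out_dir / "activation"
    act_dir.mkdir(exist_ok=True)
    for key_name, df in act.items():
        df.to_csv(act_dir / f"{key_name.replace('/', '_')}.csv", index=False)

    fc_dir = out_dir / "fc"
    fc_dir.mkdir(exist_ok=True)
    fc_results = {}
    for group in sorted(set(groups)):
        gpids = [p for p, g in zip(pids, groups) if g == group]
        for condA, condB in FC_CONTRASTS:
            usable = [
                p for p in gpids
                if condA in fc_by_pid[p] and condB in fc_by_pid[p]
            ]
            if len(usable) < 2:
                log.warning("%s %s>%s: fewer than 2 participants, skipped",
                            group, condA, condB)
                continue
            zA = [fc_by_pid[p][condA] for p in usable]
            zB = [fc_by_pid[p][condB] for p in usable]
            label = f"{group}: {condA} > {condB}"
            cm = paired_contrast(zA, zB, label=label, alpha=cfg.fc_alpha, q=cfg.fdr_q)
            stem = f"{group}_{condA}_gt_{condB}"
            for which in ("t", "p", "neglog10p"):
                contrast_to_csv(cm, fc_dir / f"{stem}_{which}.csv", which)
            if cfg.make_figures:
                render_contrast(cm, cmap, fc_dir / f"{stem}.svg")
            fc_results[stem] = cm

    report(out_dir, cmap, cfg, act, fc_results)
    return out_dir


def report(out_dir, cmap: ChannelMap, cfg: PipelineConfig,
           act: dict, fc_results: dict) -> Path:
    """Write a markdown summary: significant channels/connections with
    region labels, QC exclusions, and a config echo."""
    out_dir = Path(out_dir)
    region = {ch.channel_id: ch.region for ch in cmap.channels}
    lines = ["# Pipeline report", ""]

    lines += ["## QC summary", ""]
    qc_dir = out_dir / "qc"
    if qc_dir.exists():
        for f in sorted(qc_dir.glob("*.json")):
            info = json.loads(f.read_text())
            excl = sorted({c for blk in info.values() for c in blk["excluded_channels"]})
            lines.append(f"- {f.stem}: excluded channels {excl if excl else 'none'}")
    lines.append("")

    lines += ["## Significant activation (FDR q = %.3g)" % cfg.fdr_q, ""]
    any_sig = False
    for key_name, df in act.items():
        sig = df[df["significant"] == True]  # noqa: E712
        for _, r in sig.iterrows():
            any_sig = True
            ch = int(r["channel"])
            lines.append(
                f"- {key_name}: CH {ch} ({region.get(ch, 'n/a')}), "
                f"t = {r['t']:.2f}, corrected p = {r['p_fdr']:.4f}"
            )
    if not any_sig:
        lines.append("- none")
    lines.append("")

    lines += ["## Significant connections (uncorrected p < %.3g)" % cfg.fc_alpha, ""]
    any_conn = False
    for stem, cm in fc_results.items():
        for mask, sign in ((cm.mask_pos, "+"), (cm.mask_neg, "-")):
            for i, j in zip(*np.where(np.triu(mask, k=1))):
                any_conn = True
                ci, cj = cm.channel_ids[i], cm.channel_ids[j]
                lines.append(
                    f"- {stem} ({sign}): CH {ci} ({region.get(ci)}) - "
                    f"CH {cj} ({region.get(cj)}), t = {cm.t[i, j]:.2f}, "
                    f"p = {cm.p[i, j]:.4f}"
                )
    if not any_conn:
        lines.append("- none")
    lines.append("")

    lines += ["## Configuration", "", "```yaml",
              yaml.safe_dump(cfg.to_dict(), sort_keys=False).rstrip(), "```", ""]
    path = out_dir / "report.md"
    path.write_text("\n".join(lines))
    return path
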