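"""Trimming: remove residues of the morphed model that contradict the map.

A residue is rejected when its mean atom-position density falls below
``k_mean * rho_mean_all + k_sd * SD_mean_all`` (both statistics computed
once from the untrimmed model) or when its local map-model correlation is
below ``cc_min``.  All four constants are adjustable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field

from .density import DEFAULT_BLUR_B, DensityMap, residue_stats
from .errors import EmptyModelError
from .structure_io import AtomicModel, Chain

__all__ = ["TrimConfig", "TrimReport", "trim_model"]


class TrimConfig(BaseModel):
    """Rejection thresholds for trimming (defaults follow the method)."""
    k_mean: float = Field(0.5, ge=0)
    k_sd: float = Field(0.2)
    cc_min: float = Field(0.4, ge=-1.0, le=1.0)
    cc_sphere_radius: float = Field(2.5, gt=0)
    blur_b: float = Field(DEFAULT_BLUR_B, ge=0)


@dataclass
class TrimReport:
    """Per-residue trim decisions plus the global statistics used."""
    rows: list[dict]              # chain, seqid, rho_mean, cc, kept, reason
    rho_mean_all: float
    sd_mean_all: float
    threshold: float
    n_kept: int
    n_removed: int

    def to_tsv(self) -> str:
        lines = ["chain\tresid\trho_mean\tcc\tkept\treason"]
        for r in self.rows:
            lines.append(f"{r['chain']}\t{r['seqid']}\t{r['rho_mean']:.4f}\t"
                         f"{r['cc']:.4f}\t{int(r['kept'])}\t{r['reason']}")
        return "\n".join(lines) + "\n"


def trim_model(model: AtomicModel, dmap: DensityMap,
               cfg: TrimConfig | None = None
               ) -> tuple[AtomicModel, TrimReport]:
    """Remove residues with weak density or poor local correlation.

    The density threshold is derived once from the full untrimmed model.
    Surviving residues keep their coordinates, numbering and
    template/provenance indices untouched.
    """
    cfg = cfg or TrimConfig()
    if model.n_residues == 0:
        raise EmptyModelError("cannot trim an empty model")
    stats = residue_stats(dmap, model, blur_b=cfg.blur_b,
                          cc_radius=cfg.cc_sphere_radius)
    threshold = cfg.k_mean * stats.rho_mean_all + cfg.k_sd * stats.sd_mean_all

    rows: list[dict] = []
    out = AtomicModel()
    i = 0
    for ch in model.chains:
        new_ch = Chain(ch.id)
        for res in ch.residues:
            rho, cc = float(stats.rho_mean[i]), float(stats.cc[i])
            i += 1
            if rho < threshold:
                kept, reason = False, "low_density"
            elif cc < cfg.cc_min:
                kept, reason = False, "low_cc"
            else:
                kept, reason = True, ""
            rows.append({"chain": ch.id, "seqid": res.seqid,
                         "rho_mean": rho, "cc": cc,
                         "kept": kept, "reason": reason})
            if kept:
                new_ch.residues.append(res)
        if new_ch.residues:
            out.chains.append(new_ch)
    report = TrimReport(rows=rows, rho_mean_all=stats.rho_mean_all,
                        sd_mean_all=stats.sd_mean_all,
                        threshold=float(threshold),
                        n_kept=sum(r["kept"] for r in rows),
                        n_removed=sum(not r["kept"] for r in rows))
    out2 = out.copy()  # detach shared residue objects from the input model
    return out2, report
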