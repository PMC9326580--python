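"""End-to-end convenience wrapper: fragments + annotation + genome -> ESKOR table."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import gc_profiles, occupancy
from .io_formats import FragmentSet, GeneModel
from .occupancy import TrendFit


@dataclass
class EskorResult:
    """Filtered per-gene occupancy table plus cohort-level statistics."""

    table: pd.DataFrame  # ranked, with eskor_rank and gc_moving_avg
    filter_stages: dict[str, int]
    fit_unt: TrendFit
    fit_kd: TrendFit
    slope_drop_percent: int
    pearson_r: float


def run_eskor(
    genes: dict[str, GeneModel],
    genome,
    frags_unt: FragmentSet,
    frags_kd: FragmentSet,
    expression: pd.DataFrame | None = None,
    min_length: int = occupancy.DEFAULT_MIN_LENGTH,
    min_fpkm: float = occupancy.DEFAULT_MIN_FPKM,
    expressed: set[str] | None = None,
    smooth_window: int = occupancy.DEFAULT_SMOOTH_WINDOW,
    skip_5prime: int = gc_profiles.DEFAULT_SKIP_5PRIME,
) -> EskorResult:
    """Count, normalize, filter, and rank genes by ESKOR.

    ``expressed`` defaults to the ids backing ``expression`` (gene or isoform
    ids), mirroring the requirement that analyzed genes also appear in the
    RNA-seq list.
    """
    gc = gc_profiles.gc_table(genes, genome, skip_5prime=skip_5prime)
    table = occupancy.build_occupancy_table(
        genes, frags_unt, frags_kd, gc, expression
    )
    if expressed is None and expression is not None:
        ids = set(expression.index)
        expressed = {
            gid for gid, g in genes.items() if gid in ids or g.isoform_id in ids
        }
    filtered, stages = occupancy.filter_genes(
        table, min_length=min_length, min_fpkm=min_fpkm, expressed=expressed
    )
    filtered = occupancy.add_eskor(filtered)
    fit_unt = occupancy.fit_trend(filtered, "UNT")
    fit_kd = occupancy.fit_trend(filtered, "KD")
    ranked, r = occupancy.rank_and_smooth(filtered, window=smooth_window)
    return EskorResult(
        table=ranked,
        filter_stages=stages,
        fit_unt=fit_unt,
        fit_kd=fit_kd,
        slope_drop_percent=occupancy.slope_drop_percent(fit_unt, fit_kd),
        pearson_r=r,
    )
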