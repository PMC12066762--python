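"""Seed-to-plant tracking: IDs, trait-table joins, end-to-end runs.

Every seed batch gets a batch ID; every phenotyped seed a seed ID
embedding it; sown seeds are linked to a tray ID and x/y pot position so
that plant observations (germination, growth) can be joined back onto
the seed's own traits.  The unit of exchange is a flat CSV with one row
per seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntegrityError, DomainError
from . import seedstats, synthdata
from .growthfit import fit_linear_segment

__all__ = ["assign_ids", "join_traits", "run_end_to_end", "BatchRegistry"]

logger = logging.getLogger("seedtrack")

TRACKING_COLUMNS = ["seed_id", "batch_id", "tray_id", "pos_x", "pos_y", "plant_id"]


class BatchRegistry:
    """Tracks registered batch IDs so seed IDs stay globally unique."""

    def __init__(self):
        self._batches: dict[str, int] = {}

    def register(self, batch_id: str, n_seeds: int) -> None:
        if not batch_id:
            raise DomainError("batch_id must be non-empty")
        if batch_id in self._batches:
            raise IntegrityError(f"batch {batch_id!r} already registered")
        self._batches[batch_id] = n_seeds

    def __contains__(self, batch_id: str) -> bool:
        return batch_id in self._batches


def assign_ids(batch_id: str, n_seeds: int, registry: BatchRegistry | None = None) -> list[str]:
    """Unique, ordered seed IDs embedding the batch ID (``C-0001`` ...).

    With a registry, re-registering an existing batch raises
    :class:`IntegrityError`.
    """
    if registry is not None:
        registry.register(batch_id, n_seeds)
    elif not batch_id:
        raise DomainError("batch_id must be non-empty")
    return [f"{batch_id}-{i + 1:04d}" for i in range(n_seeds)]


def join_traits(
    seed_table: pd.DataFrame, growth_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Left-join plant observations onto the seed trait table by seed_id.

    All phenotyped seeds are preserved; growth rows without a matching
    seed are returned separately for reporting.  Duplicate seed IDs in
    either table violate referential integrity.
    """
    for name, tbl in (("seed", seed_table), ("growth", growth_table)):
        if "seed_id" not in tbl.columns:
            raise IntegrityError(f"{name} table lacks seed_id column")
        dup = tbl["seed_id"].duplicated()
        if dup.any():
            raise IntegrityError(
                f"duplicate seed_id in {name} table: {tbl['seed_id'][dup].iloc[0]!r}"
            )
    joined = seed_table.merge(growth_table, on="seed_id", how="left",
                              suffixes=("", "_growth"))
    unmatched = growth_table[~growth_table["seed_id"].isin(seed_table["seed_id"])]
    if len(unmatched):
        logger.warning("%d growth rows without a matching seed", len(unmatched))
    return joined, unmatched


def _tray_positions(n: int, layout=(5, 4)):
    """Fill trays in row-major order; returns (tray_id, x, y) per seed."""
    per_tray = layout[0] * layout[1]
    out = []
    for k in range(n):
        tray, slot = divmod(k, per_tray)
        out.append((f"T{tray + 1:03d}", slot % layout[0], slot // layout[0]))
    return out


def run_end_to_end(config: dict | str | Path, rng_seed: int = 0) -> dict:
    """Run a full synthetic tracking experiment and write its report.

    Config keys: ``batches`` (list of {name, n, summary?}; summary
    defaults to the built-in control / elevated-temperature batch
    summaries), ``out_dir``, optional ``sown_fraction`` and
    ``emerged_fraction``.  Stages: batch generation → seed IDs and tray
    positions → growth-curve simulation per sown seed → growth fitting →
    join → correlation matrix and per-trait Welch tests.  Deterministic
    given ``rng_seed``.
    """
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    if not config or "batches" not in config or not config["batches"]:
        raise DomainError("config must name at least one batch")
    out_dir = Path(config.get("out_dir", "seedtrack_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    sown_frac = float(config.get("sown_fraction", 1.0))
    rng = np.random.default_rng(rng_seed)
    registry = BatchRegistry()

    default_summaries = {"C": seedstats.CONTROL_BATCH, "T": seedstats.ELEVATED_TEMP_BATCH}
    tables = []
    for bi, bspec in enumerate(config["batches"]):
        name = bspec["name"]
        n = int(bspec["n"])
        summary = bspec.get("summary") or default_summaries.get(name, seedstats.CONTROL_BATCH)
        logger.info("stage=batch batch=%s n=%d", name, n)
        df = synthdata.make_seed_batch(summary, n=n, rng_seed=int(rng.integers(2**31)),
                                       batch_prefix=name)
        df["seed_id"] = assign_ids(name, n, registry)
        tables.append(df)
    seeds = pd.concat(tables, ignore_index=True)

    n_sown = int(round(sown_frac * len(seeds)))
    sown_idx = np.sort(rng.choice(len(seeds), size=n_sown, replace=False))
    pos = _tray_positions(n_sown)
    seeds["tray_id"] = None
    seeds["pos_x"] = pd.array([None] * len(seeds), dtype="Int64")
    seeds["pos_y"] = pd.array([None] * len(seeds), dtype="Int64")
    for (tray, x, y), i in zip(pos, sown_idx):
        seeds.loc[i, ["tray_id", "pos_x", "pos_y"]] = (tray, x, y)

    growth_rows = []
    for i in sown_idx:
        row = seeds.iloc[i]
        try:
            spec = synthdata.GrowthSpec(
                germination_time=max(row["germination_time_d"], 0.5),
                linear_rate=max(row["growth_rate_mm2_d"], 0.05),
            )
        except DomainError:
            continue
        series, _ = synthdata.make_growth_curve(spec, rng_seed=int(rng.integers(2**31)))
        fit = fit_linear_segment(series)
        growth_rows.append({
            "seed_id": row["seed_id"],
            "plant_id": f"P-{row['seed_id']}" if fit.status == "fitted" else None,
            "fit_status": fit.status,
            "germination_time_fit_d": fit.germination_time,
            "growth_rate_fit_mm2_d": fit.growth_rate,
            "adj_r2": fit.adj_r2,
        })
    growth = pd.DataFrame(growth_rows)
    logger.info("stage=growthfit fitted=%d of %d sown",
                int((growth["fit_status"] == "fitted").sum()) if len(growth) else 0, n_sown)

    records, unmatched = join_traits(seeds, growth)

    traits = [t for t in synthdata.DEFAULT_TRAIT_ORDER if t in records.columns]
    r, p, stars = seedstats.correlation_matrix(records, traits)
    batch_names = [b["name"] for b in config["batches"]]
    tests = {}
    if len(batch_names) >= 2:
        a, b = batch_names[:2]
        for t in traits:
            va = records.loc[records["batch_id"] == a, t].dropna().to_numpy()
            vb = records.loc[records["batch_id"] == b, t].dropna().to_numpy()
            if len(va) > 1 and len(vb) > 1:
                tstat, df, pval = seedstats.welch_ttest(va, vb)
                tests[t] = {"t": tstat, "df": df, "p": pval}

    records.to_csv(out_dir / "records.csv", index=False)
    r.to_csv(out_dir / "correlation_r.csv")
    report = {
        "n_seeds": int(len(seeds)),
        "n_sown": n_sown,
        "n_fitted": int((growth["fit_status"] == "fitted").sum()) if len(growth) else 0,
        "unmatched_growth_rows": int(len(unmatched)),
        "correlation_traits": traits,
        "correlation_r": r.round(4).to_dict(),
        "correlation_stars": stars.to_dict(),
        "welch_tests": tests,
        "rng_seed": rng_seed,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
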