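"""Greedy window-based LD pruning against a reference genotype panel.

Every pair of SNPs within ``window_bp`` on one chromosome whose genotype
dosages have squared Pearson correlation above ``r2_threshold`` is flagged;
flagged pairs are processed in ascending (chrom, left pos, right pos) order
and, whenever both members are still retained, one is removed by a fair
coin. The coin for each pair is drawn from a keyed hash of (seed, chrom,
positions), so a pair's outcome does not depend on which other pairs were
flagged — runs are reproducible and threshold changes comparable.

r^2 here is the squared Pearson correlation of unphased genotype dosages
(the composite/genotypic r^2 PLINK reports without phasing), computed over
pairwise-complete samples.
"""

from __future__ import annotations

import hashlib
import logging

import numpy as np
import pandas as pd

from .io import PanelGenotypes
from .types import PruneConfig, PruneResult

logger = logging.getLogger(__name__)

_MIN_COMPLETE = 4


def compute_r2(dosages_x, dosages_y):
    """Squared Pearson correlation of two dosage vectors (missing = -1).

    Returns None (undefined) when fewer than 4 pairwise-complete samples
    remain or either vector is constant over the complete samples; callers
    must treat such pairs as unflagged.
    """
    x = np.asarray(dosages_x, dtype=float)
    y = np.asarray(dosages_y, dtype=float)
    ok = (x >= 0) & (y >= 0)
    if ok.sum() < _MIN_COMPLETE:
        return None
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return None
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return min(1.0, r * r)


def _coin(seed: int, chrom, pos_left: int, pos_right: int) -> int:
    """Fair, seed-keyed coin for one flagged pair: 0 removes left, 1 right."""
    key = int(seed).to_bytes(8, "little", signed=True)
    msg = f"{chrom}:{pos_left}:{pos_right}".encode()
    digest = hashlib.blake2b(msg, key=key, digest_size=8).digest()
    return digest[0] & 1


def _flag_pairs(snps: pd.DataFrame, panel: PanelGenotypes, config: PruneConfig):
    """All within-window pairs with r^2 above threshold, in canonical order.

    Returns (pairs, n_untested): pairs as (chrom, pos_left, pos_right,
    id_left, id_right); n_untested counts SNPs absent from the panel, which
    pass through unflagged.
    """
    pairs = []
    n_untested = 0
    for chrom, grp in snps.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        in_panel = np.array([(chrom, int(p)) in panel for p in grp["pos"]])
        n_untested += int((~in_panel).sum())
        grp = grp.loc[in_panel]
        if len(grp) < 2:
            continue
        positions = grp["pos"].to_numpy()
        ids = grp["snp_id"].to_numpy()
        rows = np.array([panel.row(chrom, int(p)) for p in positions])
        dos = panel.dosages[rows].astype(float)
        missing = dos < 0
        if not missing.any():
            # fast path: standardized rows, correlation by dot product
            mean = dos.mean(axis=1, keepdims=True)
            sd = dos.std(axis=1, keepdims=True)
            const = sd[:, 0] == 0
            sd[sd == 0] = 1.0
            z = (dos - mean) / sd
            nsamp = dos.shape[1]
            hi = np.searchsorted(positions, positions + config.window_bp, side="right")
            for i in range(len(positions)):
                if const[i] or hi[i] <= i + 1:
                    continue
                js = np.arange(i + 1, hi[i])
                js = js[~const[js]]
                if js.size == 0:
                    continue
                r = z[js] @ z[i] / nsamp
                for j in js[r * r > config.r2_threshold]:
                    pairs.append((chrom, int(positions[i]), int(positions[j]), ids[i], ids[int(j)]))
        else:
            hi = np.searchsorted(positions, positions + config.window_bp, side="right")
            for i in range(len(positions)):
                for j in range(i + 1, hi[i]):
                    r2 = compute_r2(dos[i], dos[j])
                    if r2 is not None and r2 > config.r2_threshold:
                        pairs.append((chrom, int(positions[i]), int(positions[j]), ids[i], ids[j]))
    pairs.sort(key=lambda t: (str(t[0]), t[1], t[2]))
    return pairs, n_untested


def prune(snps: pd.DataFrame, panel: PanelGenotypes, config: PruneConfig | None = None) -> PruneResult:
    """Greedily prune SNPs until no within-window pair exceeds the threshold.

    ``snps`` needs columns snp_id/chrom/pos. SNPs not resolvable in the
    panel (or with undefined r^2) are retained untested and counted —
    dropping them silently would bias the enrichment denominator.
    """
    if config is None:
        config = PruneConfig()
    if len(snps) == 0:
        return PruneResult(frozenset(), frozenset(), 0, config.seed, 0)
    pairs, n_untested = _flag_pairs(snps, panel, config)
    removed = set()
    for chrom, pos_l, pos_r, id_l, id_r in pairs:
        if id_l in removed or id_r in removed:
            continue
        removed.add(id_r if _coin(config.seed, chrom, pos_l, pos_r) else id_l)
    retained = frozenset(snps["snp_id"]) - removed
    logger.info(
        "prune: %d flagged pairs, %d removed, %d retained, %d untested",
        len(pairs),
        len(removed),
        len(retained),
        n_untested,
    )
    return PruneResult(
        retained=retained,
        removed=frozenset(removed),
        n_pairs_flagged=len(pairs),
        seed=config.seed,
        n_untested=n_untested,
    )
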