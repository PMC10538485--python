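"""VCF/BED input, theta estimation and posterior output.

Coordinates: VCF positions are 1-based; BED intervals are 0-based half-open;
everything internal is 0-based.  A site is missing for a haplotype pair if
it lies outside the intersection of the two samples' accessibility masks; a
biallelic SNP inside the masks is het when the two haplotype alleles differ;
every other masked-in position is hom.  Multiallelic records, indels and
(by default) non-PASS records are treated as missing.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core_model import Observation
from .engine import PosteriorTrack

__all__ = [
    "RunConfig",
    "Haplotype",
    "read_pair_observations",
    "estimate_theta",
    "write_posteriors",
    "read_posteriors",
    "write_tracks_tsv",
    "all_haplotype_pairs",
    "n_haplotype_pairs",
]

#: a haplotype is (sample name, 0 or 1)
Haplotype = Tuple[str, int]


@dataclass
class RunConfig:
    """Parameters of a decoding run."""

    vcf: str
    masks: str | Dict[str, str] | None = None
    theta: float | None = None
    rho: float | None = None
    rho_over_theta: float | None = None
    output_mode: str = "grid"          # "grid" | "het" | "both"
    grid_spacing: int = 1_000
    pair_selection: str = "within-diploid"  # "all" | "within-diploid"
    samples: List[str] | None = None
    Ne: float = 15_000.0
    generation_time: float = 30.0
    max_len: int = 10_000
    keep_non_pass: bool = False

    def __post_init__(self) -> None:
        if self.grid_spacing < 1:
            raise ValueError("grid spacing must be >= 1")
        if self.theta is None and self.rho is None and self.rho_over_theta is None:
            # theta will be estimated from the data; rho then needs the ratio
            pass

    def resolve_rates(self, estimated_theta: float | None = None) -> Tuple[float, float]:
        theta = self.theta if self.theta is not None else estimated_theta
        if theta is None:
            raise ValueError("theta not given and not estimable")
        rho = self.rho
        if rho is None and self.rho_over_theta is not None:
            rho = self.rho_over_theta * theta
        if rho is None:
            raise ValueError("provide rho or rho/theta ratio")
        return theta, rho


def _read_bed_intervals(path: str, chrom: str) -> List[Tuple[int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if f[0] == chrom:
                out.append((int(f[1]), int(f[2])))
    return sorted(out)


def _mask_array(path: str | None, chrom: str, start: int, end: int) -> np.ndarray:
    """Boolean accessibility over [start, end); True = inside the mask."""
    if path is None:
        return np.ones(end - start, dtype=bool)
    acc = np.zeros(end - start, dtype=bool)
    for a, b in _read_bed_intervals(path, chrom):
        a = max(a, start)
        b = min(b, end)
        if b > a:
            acc[a - start:b - start] = True
    return acc


def _mask_for_sample(masks, sample: str) -> str | None:
    if masks is None:
        return None
    if isinstance(masks, dict):
        return masks.get(sample)
    return masks  # single global BED


def read_pair_observations(vcf_path: str, masks, region: Tuple[str, int, int],
                           hapA: Haplotype, hapB: Haplotype,
                           keep_non_pass: bool = False) -> np.ndarray:
    """Per-bp observation sequence for one haplotype pair.

    ``region`` is (chrom, start, end), 0-based half-open.  Cross-individual
    pairs require phased genotypes; within-individual pairs do not (het/hom
    status is phase-invariant).
    """
    from cyvcf2 import VCF

    chrom, start, end = region
    sampleA, idxA = hapA
    sampleB, idxB = hapB
    if idxA not in (0, 1) or idxB not in (0, 1):
        raise ValueError("haplotype index must be 0 or 1")

    acc = (_mask_array(_mask_for_sample(masks, sampleA), chrom, start, end)
           & _mask_array(_mask_for_sample(masks, sampleB), chrom, start, end))
    obs = np.where(acc, np.uint8(Observation.HOM), np.uint8(Observation.MISSING))

    vcf = VCF(vcf_path)
    samples = vcf.samples
    try:
        ia = samples.index(sampleA)
        ib = samples.index(sampleB)
    except ValueError as exc:
        raise ValueError(f"sample not found in VCF: {exc}") from exc
    cross = sampleA != sampleB

    # region queries need a tabix/CSI index; fall back to a full scan for
    # plain-text VCFs
    indexed = str(vcf_path).endswith(".gz") and (
        os.path.exists(str(vcf_path) + ".tbi") or os.path.exists(str(vcf_path) + ".csi"))
    records = vcf(f"{chrom}:{start + 1}-{end}") if indexed else vcf
    for rec in records:
        if rec.CHROM != chrom:
            continue
        pos = rec.POS - 1  # to 0-based
        if pos < start or pos >= end or not acc[pos - start]:
            continue
        if rec.FILTER is not None and not keep_non_pass:  # cyvcf2: None == PASS/.
            obs[pos - start] = Observation.MISSING
            continue
        if not rec.is_snp or len(rec.ALT) != 1:
            obs[pos - start] = Observation.MISSING
            continue
        ga = rec.genotypes[ia]
        gb = rec.genotypes[ib]
        # cyvcf2 genotype: [allele0, allele1, phased]
        if ga[0] < 0 or ga[1] < 0 or gb[0] < 0 or gb[1] < 0:
            obs[pos - start] = Observation.MISSING
            continue
        if cross and not (ga[2] and gb[2]):
            raise ValueError(
                f"unphased genotype at {chrom}:{rec.POS} for cross-individual pair "
                f"{sampleA}/{sampleB}; phased input is required"
            )
        a = ga[idxA]
        b = gb[idxB]
        obs[pos - start] = Observation.HET if a != b else Observation.HOM
    return obs


def estimate_theta(obs_list: Sequence[np.ndarray]) -> float:
    """Average heterozygosity across pairs: mean of het count / unmasked bp."""
    if not obs_list:
        raise ValueError("need at least one pair")
    rates = []
    for obs in obs_list:
        unmasked = int((obs != Observation.MISSING).sum())
        if unmasked == 0:
            raise ValueError("pair with zero unmasked length")
        rates.append(int((obs == Observation.HET).sum()) / unmasked)
    return float(np.mean(rates))


def all_haplotype_pairs(samples: Sequence[str],
                        within_diploid: bool = False) -> List[Tuple[Haplotype, Haplotype]]:
    """Enumerate unordered haplotype pairs over the given samples."""
    haps: List[Haplotype] = [(s, i) for s in samples for i in (0, 1)]
    if within_diploid:
        return [((s, 0), (s, 1)) for s in samples]
    return [(haps[i], haps[j]) for i in range(len(haps)) for j in range(i + 1, len(haps))]


def n_haplotype_pairs(n_haplotypes: int) -> int:
    """Number of unordered pairs among n haplotypes: n(n-1)/2."""
    return n_haplotypes * (n_haplotypes - 1) // 2


def write_posteriors(tracks: Sequence[PosteriorTrack], path: str,
                     params: dict | None = None) -> None:
    """Binary posterior sink: compressed npz with a JSON header.

    Stores (alpha, beta) per pair per position losslessly, plus positions,
    the pair list and run parameters.  Written atomically via a temp file.
    """
    header = {
        "format": "gammasmc-posteriors",
        "version": 1,
        "pairs": [list(map(str, t.pair)) for t in tracks],
        "params": params or {},
    }
    arrays = {"header": np.array(json.dumps(header))}
    if tracks:
        positions = tracks[0].positions
        for t in tracks[1:]:
            if not np.array_equal(t.positions, positions):
                raise ValueError("all tracks must share output positions")
        arrays["positions"] = positions
        arrays["alpha"] = np.stack([t.alpha for t in tracks])
        arrays["beta"] = np.stack([t.beta for t in tracks])
        arrays["fwd_alpha"] = np.stack([t.fwd_alpha for t in tracks])
        arrays["fwd_beta"] = np.stack([t.fwd_beta for t in tracks])
        arrays["bwd_alpha"] = np.stack([t.bwd_alpha for t in tracks])
        arrays["bwd_beta"] = np.stack([t.bwd_beta for t in tracks])
    else:
        arrays["positions"] = np.array([], dtype=np.int64)
    tmp_fd, tmp_path = tempfile.mkstemp(dir=os.path.dirname(os.path.abspath(path)) or ".",
                                        suffix=".tmp.npz")
    os.close(tmp_fd)
    try:
        np.savez_compressed(tmp_path, **arrays)
        os.replace(tmp_path, path)
    finally:
        if os.path.exists(tmp_path):
            os.remove(tmp_path)


def read_posteriors(path: str):
    """Read a posterior file back; returns (header dict, positions, arrays dict)."""
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        if header.get("format") != "gammasmc-posteriors":
            raise ValueError("not a gammasmc posterior file")
        arrays = {k: z[k] for k in z.files if k != "header"}
    return header, arrays.pop("positions"), arrays


def write_tracks_tsv(tracks: Sequence[PosteriorTrack], path: str, chrom: str = "1") -> None:
    """Optional flat TSV sink, one row per (pair, position), sorted."""
    import pandas as pd

    rows = []
    for t in sorted(tracks, key=lambda t: tuple(map(str, t.pair))):
        for k, pos in enumerate(t.positions):
            rows.append((chrom, int(pos), str(t.pair[0]), str(t.pair[1]),
                         t.alpha[k], t.beta[k],
                         t.mean_generations[k] if t.mean_generations is not None else np.nan,
                         t.mean_years[k] if t.mean_years is not None else np.nan))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "hapA", "hapB", "alpha", "beta",
                                     "post_mean_generations", "post_mean_years"])
    df.to_csv(path, sep="\t", index=False)
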