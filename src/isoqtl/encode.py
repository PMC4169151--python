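"""Construction of the two multiparental mapping datasets.

From one trimmed raw allele-count matrix, two dialects are built:

* the **GWAS dataset** keeps the shared 0/1/2 coding of a fixed reference
  allele across families (a SNP may be fixed at 0 in one family and at 2 in
  another), with residual missing cells filled by the rounded within-family
  mean so that no missing data remain;

* the **linkage dataset** re-codes each family relative to its own parents
  (SC homozygote = 0, EP homozygote = 2, heterozygote = 1), sets
  within-family-monomorphic SNPs missing, masks chromosomes and regions
  longer than 10 Mb without a polymorphic marker as non-segregating, and
  imputes the remaining missing cells as the mean of the nearest flanking
  markers weighted by physical (bp) distance.

Trimming removes SNPs with more than 5% missing data, then collapses runs
of adjacent SNPs closer than 64 bp with bit-identical genotype columns.
All three thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, SnpMap


class EncodingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------

def trim_snps(gm: GenotypeMatrix, max_missing: float = 0.05,
              collapse_bp: int = 64):
    """Drop high-missingness SNPs, then collapse near-duplicate neighbours.

    A SNP is dropped if its missing fraction is strictly greater than
    ``max_missing``.  Then, scanning each chromosome in position order, a
    SNP strictly closer than ``collapse_bp`` downstream of the previously
    *retained* SNP is dropped when its genotype column (including the
    missing pattern) is identical; the left-most SNP of such a pair is the
    one retained.

    Returns ``(trimmed GenotypeMatrix, log DataFrame)`` where the log lists
    every removed SNP with its reason.
    """
    codes = gm.codes
    smap = gm.snp_map
    miss_frac = np.isnan(codes).mean(axis=0)
    keep = miss_frac <= max_missing
    log = [
        {"snp_id": smap.snp_id[j], "reason": "missing",
         "detail": f"missing fraction {miss_frac[j]:.4f} > {max_missing}"}
        for j in np.flatnonzero(~keep)
    ]
    idx = np.flatnonzero(keep)
    retained = []
    for j in idx:
        if retained:
            k = retained[-1]
            same_chrom = smap.chrom[j] == smap.chrom[k]
            if (same_chrom and smap.pos_bp[j] - smap.pos_bp[k] < collapse_bp
                    and np.array_equal(codes[:, j], codes[:, k], equal_nan=True)):
                log.append({"snp_id": smap.snp_id[j], "reason": "duplicate",
                            "detail": f"identical to {smap.snp_id[k]} at "
                                      f"{smap.pos_bp[j] - smap.pos_bp[k]} bp"})
                continue
        retained.append(int(j))
    out = gm.subset_snps(np.array(retained, dtype=int))
    return out, pd.DataFrame(log, columns=["snp_id", "reason", "detail"])


# ---------------------------------------------------------------------------
# Parent-of-origin polarization
# ---------------------------------------------------------------------------

@dataclass
class PolarizedFamily:
    """Linkage-coded matrix for one family, before masking/imputation."""

    values: np.ndarray        # (n_lines, n_snps) float, NaN = missing
    monomorphic: np.ndarray   # (n_snps,) bool: parents agree at this SNP
    n_nonparental: int        # progeny cells carrying an allele of neither parent


def polarize_by_parent(progeny: np.ndarray, sc_parent: np.ndarray,
                       ep_parent: np.ndarray) -> PolarizedFamily:
    """Re-code one family's raw 0/1/2 counts relative to its parents.

    Alleles matching the SC parent count 0 per copy, those matching the EP
    parent count 2; heterozygotes become 1.  SNPs where the parents agree
    (monomorphic within the family) become entirely missing.  Progeny
    alleles present in neither parent are counted and set missing.  Parents
    must be homozygous (codes 0 or 2) at every SNP.
    """
    progeny = np.asarray(progeny, dtype=np.float64)
    sc = np.asarray(sc_parent, dtype=np.float64)
    ep = np.asarray(ep_parent, dtype=np.float64)
    if progeny.ndim != 2 or progeny.shape[1] != sc.size or sc.size != ep.size:
        raise EncodingError("progeny/parent dimensions do not match")
    if not (np.isin(sc, (0.0, 2.0)).all() and np.isin(ep, (0.0, 2.0)).all()):
        raise EncodingError("parent genotypes must be homozygous (0 or 2)")
    mono = sc == ep
    values = np.where(ep == 2.0, progeny, 2.0 - progeny)
    nonpar = ~np.isnan(progeny) & mono[None, :] & (progeny != sc[None, :])
    values[:, mono] = np.nan
    return PolarizedFamily(values, mono, int(nonpar.sum()))


# ---------------------------------------------------------------------------
# Non-segregating region masking
# ---------------------------------------------------------------------------

def mask_nonsegregating(polarized: np.ndarray, snp_map: SnpMap,
                        min_gap_mb: float = 10.0):
    """Mask regions > ``min_gap_mb`` Mb without a polymorphic marker.

    A column counts as monomorphic when it is entirely missing after
    polarization.  A maximal run of monomorphic SNPs is masked when the gap
    between its flanking polymorphic markers (or the run's own extent at a
    chromosome end) strictly exceeds the threshold; chromosomes without any
    polymorphic marker are masked whole.  Masked cells stay missing and are
    never bridged by imputation.

    Returns ``(mask, regions)``: a per-SNP boolean mask and a list of
    0-based half-open ``(chrom, start, end)`` intervals.
    """
    mono = np.isnan(polarized).all(axis=0)
    mask = np.zeros(snp_map.n_snps, dtype=bool)
    regions = []
    threshold = float(min_gap_mb) * 1e6
    for chrom in snp_map.chromosomes:
        sl = snp_map.chrom_slice(chrom)
        cmono = mono[sl]
        pos = snp_map.pos_bp[sl]
        if cmono.all():
            mask[sl] = True
            regions.append((chrom, int(pos[0]) - 1, int(pos[-1])))
            continue
        j = 0
        n = cmono.size
        while j < n:
            if not cmono[j]:
                j += 1
                continue
            k = j
            while k + 1 < n and cmono[k + 1]:
                k += 1
            left = pos[j - 1] if j > 0 else pos[j]
            right = pos[k + 1] if k + 1 < n else pos[k]
            if right - left > threshold:
                mask[sl.start + j: sl.start + k + 1] = True
                regions.append((chrom, int(pos[j]) - 1, int(pos[k])))
            j = k + 1
    return mask, regions


# ---------------------------------------------------------------------------
# Distance-weighted imputation
# ---------------------------------------------------------------------------

def impute_weighted(values: np.ndarray, snp_map: SnpMap,
                    masked: np.ndarray | None = None) -> np.ndarray:
    """Fill missing cells from the nearest flanking markers, weighted by bp.

    A missing cell between two non-missing cells of the same line, at
    distances d_L and d_R with values v_L and v_R, receives
    ``(v_L * d_R + v_R * d_L) / (d_L + d_R)``; a cell with a single flank
    takes that flank's value.  Only original (non-imputed) values serve as
    flanks, distances are physical (bp), and interpolation never crosses a
    chromosome boundary or a masked region.  Cells in masked columns stay
    missing.
    """
    values = np.asarray(values, dtype=np.float64)
    out = values.copy()
    if masked is None:
        masked = np.zeros(snp_map.n_snps, dtype=bool)
    for chrom in snp_map.chromosomes:
        sl = snp_map.chrom_slice(chrom)
        cmask = masked[sl]
        pos = snp_map.pos_bp[sl].astype(np.float64)
        # contiguous unmasked index blocks; masked regions are never bridged
        for block in _unmasked_blocks(cmask):
            b = slice(sl.start + block.start, sl.start + block.stop)
            out[:, b] = _interpolate_block(values[:, b], pos[block])
    return out


def _unmasked_blocks(cmask: np.ndarray):
    blocks = []
    j = 0
    n = cmask.size
    while j < n:
        if cmask[j]:
            j += 1
            continue
        k = j
        while k + 1 < n and not cmask[k + 1]:
            k += 1
        blocks.append(slice(j, k + 1))
        j = k + 1
    return blocks


def _interpolate_block(vals: np.ndarray, pos: np.ndarray) -> np.ndarray:
    out = vals.copy()
    for i in range(vals.shape[0]):
        row = vals[i]
        obs = ~np.isnan(row)
        n_obs = int(obs.sum())
        if n_obs == 0 or n_obs == row.size:
            continue
        pos_obs = pos[obs]
        val_obs = row[obs]
        miss = np.flatnonzero(~obs)
        right = np.searchsorted(pos_obs, pos[miss])
        left = right - 1
        has_l = left >= 0
        has_r = right < pos_obs.size
        fill = np.empty(miss.size)
        both = has_l & has_r
        if both.any():
            d_l = pos[miss[both]] - pos_obs[left[both]]
            d_r = pos_obs[right[both]] - pos[miss[both]]
            v_l = val_obs[left[both]]
            v_r = val_obs[right[both]]
            fill[both] = (v_l * d_r + v_r * d_l) / (d_l + d_r)
        only_l = has_l & ~has_r
        only_r = has_r & ~has_l
        fill[only_l] = val_obs[left[only_l]]
        fill[only_r] = val_obs[right[only_r]]
        out[i, miss] = fill
    return out


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class GwasDataset:
    """All families on the shared reference-allele 0/1/2 coding, no missing."""

    matrix: GenotypeMatrix

    @property
    def families(self):
        return self.matrix.families

    def segregation_state(self, family) -> np.ndarray:
        """Per-SNP code: 0 = fixed reference homozygote, 2 = fixed
        alternative homozygote, 1 = segregating within the family."""
        rows = self.matrix.family_rows(family)
        sub = self.matrix.codes[rows]
        state = np.ones(sub.shape[1], dtype=np.int8)
        fixed = np.nanmax(sub, axis=0) == np.nanmin(sub, axis=0)
        state[fixed & (sub[0] == 0.0)] = 0
        state[fixed & (sub[0] == 2.0)] = 2
        return state


@dataclass
class LinkageDataset:
    """Per-family parent-of-origin codes with segregation masks.

    ``seg[family]`` is True at SNPs scanned for that family (i.e. outside
    masked non-segregating regions); masked cells are missing in the
    matrix.  ``masked_regions`` lists ``(chrom, start, end, family)``
    intervals, 0-based half-open.
    """

    matrix: GenotypeMatrix
    seg: dict
    masked_regions: list
    n_nonparental: dict

    @property
    def families(self):
        return self.matrix.families


def build_gwas_dataset(gm: GenotypeMatrix) -> GwasDataset:
    """Fill residual missing cells of the trimmed raw matrix.

    Each missing cell receives the within-family SNP mean rounded to the
    nearest integer (preserving the within-family allele frequency);
    families without any observed call at a SNP fall back to the overall
    SNP mean.  Monomorphic-within-family SNPs keep their fixed 0/2 code.
    """
    codes = gm.codes.copy()
    col_mean = np.nanmean(np.where(np.isnan(codes), np.nan, codes), axis=0)
    col_mean = np.where(np.isnan(col_mean), 1.0, col_mean)
    for fam in gm.families:
        rows = gm.family_rows(fam)
        sub = codes[rows]
        with np.errstate(invalid="ignore"):
            fam_mean = np.nanmean(sub, axis=0)
        fam_mean = np.where(np.isnan(fam_mean), col_mean, fam_mean)
        fill = np.clip(np.floor(fam_mean + 0.5), 0.0, 2.0)
        miss = np.isnan(sub)
        sub[miss] = np.broadcast_to(fill, sub.shape)[miss]
        codes[rows] = sub
    out = GenotypeMatrix(codes, gm.line_id, gm.family, gm.snp_map, "gwas")
    return GwasDataset(out)


def build_linkage_dataset(gm: GenotypeMatrix, parents: dict,
                          min_gap_mb: float = 10.0) -> LinkageDataset:
    """Polarize, mask and impute every family of a trimmed raw matrix.

    ``parents`` maps family name to its ``(sc, ep)`` 0/2 genotype vectors
    aligned to the matrix columns.
    """
    codes = np.full_like(gm.codes, np.nan)
    seg, regions, nonpar = {}, [], {}
    for fam in gm.families:
        if fam not in parents:
            raise EncodingError(f"no parent genotypes for family {fam!r}")
        rows = gm.family_rows(fam)
        sc, ep = parents[fam]
        pol = polarize_by_parent(gm.codes[rows], sc, ep)
        mask, fam_regions = mask_nonsegregating(pol.values, gm.snp_map, min_gap_mb)
        filled = impute_weighted(pol.values, gm.snp_map, mask)
        codes[rows] = filled
        seg[fam] = ~mask
        regions.extend((c, s, e, fam) for c, s, e in fam_regions)
        nonpar[fam] = pol.n_nonparental
    matrix = GenotypeMatrix(codes, gm.line_id, gm.family, gm.snp_map, "linkage")
    return LinkageDataset(matrix, seg, regions, nonpar)


# ---------------------------------------------------------------------------
# Parent QC
# ---------------------------------------------------------------------------

def percent_ibs(a: np.ndarray, b: np.ndarray) -> float:
    """Percent identity-by-state between two genotype vectors.

    100 x (positions with identical non-missing codes) / (positions
    non-missing in both).  Raises on zero overlap.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise EncodingError("vectors must have equal length")
    both = ~np.isnan(a) & ~np.isnan(b)
    if not both.any():
        raise EncodingError("no overlapping non-missing positions")
    return float(100.0 * (a[both] == b[both]).mean())
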