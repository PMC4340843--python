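"""Per-pair contact descriptors from structure exposure and paired MSAs.

For every candidate surface residue pair (one residue per partner) a set of
base descriptors is computed:

==  ==========================  =============================================
#   name                        quantity
==  ==========================  =============================================
1   area_full_max               max full-residue exposed area of the pair
2   area_full_min               min full-residue exposed area
3   area_side_max               max side-chain exposed area
4   area_side_min               min side-chain exposed area
5   subst_max                   max per-residue substitution score (Gonnet,
                                query amino acid vs matched-row amino acids)
6   subst_min                   min of the same
7   subst_rel_max               subst_max minus that protein's mean score
8   subst_rel_min               subst_min minus that protein's mean score
9   contact_vol1                volume-normalized inter-residue contact score
10  contact_vol2                second volume-normalized contact score
11  contact_prop_allatom        all-atom contact propensity
12  contact_prop_calpha         alpha-carbon contact propensity
13  gap_frac_max                max column gap fraction of the pair
14  gap_frac_min                min column gap fraction
15  gap_share_max               max column gap count / total alignment gaps
16  gap_share_min               min of the same
17  cooccurrence                pairwise co-occurrence log-odds score
==  ==========================  =============================================

Descriptors 9-12 average a 20x20 pair-score table over matched row pairs;
descriptor 17 is the mean log-odds of the observed amino-acid co-occurrence
versus the product of the column marginals (+1 pseudocounts), applied to the
amino-acid pair only, ignoring sequence neighbours.

Each base descriptor is then aggregated over the spatial neighborhoods of
the two residues ("all to one" and "all to all" averages), tripling the
feature count (17 base descriptors -> 51 features by default).

The Gonnet substitution matrix comes from Biopython.  The four packaged
pair-score tables (``condock/data/synthetic_contact_*.csv``) are clearly
labelled SYNTHETIC stand-ins constructed from the Kyte-Doolittle hydropathy
scale and Zamyatnin residue volumes; pass your own 20x20 CSVs (rows and
columns in ``ACDEFGHIKLMNPQRSTVWY`` order) via :class:`ScoreTables` to use
literature tables instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .msa import PairedAlignment
from .structure import NeighborhoodMap, ResidueAreas, ResidueId, Structure

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

BASE_DESCRIPTORS: tuple[str, ...] = (
    "area_full_max", "area_full_min", "area_side_max", "area_side_min",
    "subst_max", "subst_min", "subst_rel_max", "subst_rel_min",
    "contact_vol1", "contact_vol2",
    "contact_prop_allatom", "contact_prop_calpha",
    "gap_frac_max", "gap_frac_min", "gap_share_max", "gap_share_min",
    "cooccurrence",
)


def feature_names(base: tuple[str, ...] = BASE_DESCRIPTORS) -> list[str]:
    """Base + all-to-one + all-to-all feature names, in canonical order."""
    return (
        list(base)
        + [f"{d}_a2o" for d in base]
        + [f"{d}_a2a" for d in base]
    )


def _load_packaged_table(filename: str) -> np.ndarray:
    with resources.files("condock.data").joinpath(filename).open() as fh:
        df = pd.read_csv(fh, index_col=0)
    df = df.loc[list(AA_ORDER), list(AA_ORDER)]
    return df.to_numpy(dtype=float)


def load_pair_table(path: str) -> np.ndarray:
    """Load a user 20x20 pair-score CSV (amino-acid row/column labels)."""
    df = pd.read_csv(path, index_col=0)
    missing = set(AA_ORDER) - set(df.index)
    if missing:
        raise ValueError(f"pair table misses amino acids: {sorted(missing)}")
    return df.loc[list(AA_ORDER), list(AA_ORDER)].to_numpy(dtype=float)


def _gonnet_matrix() -> np.ndarray:
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("GONNET1992")
    out = np.zeros((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            out[i, j] = m[a, b]
    return out


@dataclass
class ScoreTables:
    """The 20x20 score tables feeding the alignment descriptors."""

    gonnet: np.ndarray
    contact_vol1: np.ndarray
    contact_vol2: np.ndarray
    contact_prop_allatom: np.ndarray
    contact_prop_calpha: np.ndarray

    @classmethod
    def default(cls) -> "ScoreTables":
        """Gonnet from Biopython plus the packaged synthetic contact tables."""
        return cls(
            gonnet=_gonnet_matrix(),
            contact_vol1=_load_packaged_table("synthetic_contact_volume_norm_1.csv"),
            contact_vol2=_load_packaged_table("synthetic_contact_volume_norm_2.csv"),
            contact_prop_allatom=_load_packaged_table(
                "synthetic_contact_propensity_allatom.csv"
            ),
            contact_prop_calpha=_load_packaged_table(
                "synthetic_contact_propensity_calpha.csv"
            ),
        )


def encode_alignment_rows(seqs: list[str]) -> np.ndarray:
    """Integer-encode gapped sequences: 0-19 amino acids, -1 gap/unknown."""
    n_rows = len(seqs)
    n_cols = len(seqs[0]) if seqs else 0
    out = np.full((n_rows, n_cols), -1, dtype=np.int8)
    for r, seq in enumerate(seqs):
        for c, aa in enumerate(seq):
            out[r, c] = AA_INDEX.get(aa, -1)
    return out


def residue_column_map(
    structure: Structure, chain: str, pos_to_col: dict[int, int]
) -> dict[ResidueId, int]:
    """Lift a chain-position -> column map to residue ids of that chain."""
    chain_residues = [r.rid for r in structure.residues if r.chain == chain]
    return {
        rid: pos_to_col[k]
        for k, rid in enumerate(chain_residues)
        if k in pos_to_col
    }


@dataclass
class _SideContext:
    """Precomputed per-column quantities for one partner's alignment side."""

    encoded: np.ndarray          # (n_matched, n_cols)
    query_encoded: np.ndarray    # (n_cols,)
    subst: np.ndarray            # mean Gonnet score per column (NaN if all-gap)
    subst_mean: float            # protein-wide mean substitution score
    gap_frac: np.ndarray
    gap_share: np.ndarray


def _side_context(
    encoded: np.ndarray,
    query_row: str,
    mapped_cols: list[int],
    gonnet: np.ndarray,
) -> _SideContext:
    n_rows, n_cols = encoded.shape
    query = np.array([AA_INDEX.get(aa, -1) for aa in query_row], dtype=np.int8)
    subst = np.full(n_cols, np.nan)
    gap_frac = np.zeros(n_cols)
    gap_share = np.zeros(n_cols)
    gap_counts = (encoded == -1).sum(axis=0).astype(float)
    total_gaps = gap_counts.sum()
    for c in range(n_cols):
        gap_frac[c] = gap_counts[c] / n_rows
        gap_share[c] = gap_counts[c] / total_gaps if total_gaps > 0 else 0.0
        q = query[c]
        if q < 0:
            continue
        col = encoded[:, c]
        valid = col >= 0
        if valid.any():
            subst[c] = gonnet[q, col[valid]].mean()
    mapped_subst = [subst[c] for c in mapped_cols if not np.isnan(subst[c])]
    subst_mean = float(np.mean(mapped_subst)) if mapped_subst else 0.0
    return _SideContext(encoded, query, subst, subst_mean, gap_frac, gap_share)


def _nan_max(*vals: float) -> float:
    ok = [v for v in vals if not np.isnan(v)]
    return max(ok) if ok else np.nan


def _nan_min(*vals: float) -> float:
    ok = [v for v in vals if not np.isnan(v)]
    return min(ok) if ok else np.nan


def _pair_table_mean(
    table: np.ndarray, col_a: np.ndarray, col_b: np.ndarray
) -> float:
    valid = (col_a >= 0) & (col_b >= 0)
    if not valid.any():
        return np.nan
    return float(table[col_a[valid], col_b[valid]].mean())


def _cooccurrence_score(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Mean log-odds of observed pair frequency vs product of marginals.

    +1 pseudocounts on joint (over 400 cells) and marginal (over 20 cells)
    counts keep the score finite; rows with a gap in either column are
    skipped.
    """
    valid = (col_a >= 0) & (col_b >= 0)
    if not valid.any():
        return np.nan
    a, b = col_a[valid].astype(int), col_b[valid].astype(int)
    n = a.size
    joint = np.bincount(a * 20 + b, minlength=400).reshape(20, 20)
    marg_a = np.bincount(a, minlength=20)
    marg_b = np.bincount(b, minlength=20)
    f_joint = (joint + 1) / (n + 400)
    f_a = (marg_a + 1) / (n + 20)
    f_b = (marg_b + 1) / (n + 20)
    log_odds = np.log(f_joint[a, b]) - np.log(f_a[a]) - np.log(f_b[b])
    return float(log_odds.mean())


def compute_base_descriptors(
    pairs: list[tuple[ResidueId, ResidueId]],
    pa: PairedAlignment,
    col_map_a: dict[ResidueId, int],
    col_map_b: dict[ResidueId, int],
    areas_a: ResidueAreas,
    areas_b: ResidueAreas,
    tables: ScoreTables | None = None,
) -> pd.DataFrame:
    """Base descriptor matrix for candidate pairs (one row per pair).

    Pairs whose residues lack a mapped alignment column must be excluded
    beforehand.  Descriptors that cannot be computed (e.g. a column gapped
    in every matched row) are returned as NaN for downstream imputation.
    """
    if tables is None:
        tables = ScoreTables.default()
    rows_a, rows_b = zip(*pa.matched_rows()) if pa.matched else ((), ())
    enc_a = encode_alignment_rows(list(rows_a))
    enc_b = encode_alignment_rows(list(rows_b))
    ctx_a = _side_context(enc_a, pa.a.query, sorted(set(col_map_a.values())),
                          tables.gonnet)
    ctx_b = _side_context(enc_b, pa.b.query, sorted(set(col_map_b.values())),
                          tables.gonnet)

    records = []
    for rid_a, rid_b in pairs:
        ca, cb = col_map_a[rid_a], col_map_b[rid_b]
        fa, sa = areas_a[rid_a]
        fb, sb = areas_b[rid_b]
        subst_a, subst_b = ctx_a.subst[ca], ctx_b.subst[cb]
        col_a, col_b = ctx_a.encoded[:, ca], ctx_b.encoded[:, cb]
        rec = {
            "area_full_max": max(fa, fb),
            "area_full_min": min(fa, fb),
            "area_side_max": max(sa, sb),
            "area_side_min": min(sa, sb),
            "subst_max": _nan_max(subst_a, subst_b),
            "subst_min": _nan_min(subst_a, subst_b),
            "subst_rel_max": _nan_max(
                subst_a - ctx_a.subst_mean, subst_b - ctx_b.subst_mean
            ),
            "subst_rel_min": _nan_min(
                subst_a - ctx_a.subst_mean, subst_b - ctx_b.subst_mean
            ),
            "contact_vol1": _pair_table_mean(tables.contact_vol1, col_a, col_b),
            "contact_vol2": _pair_table_mean(tables.contact_vol2, col_a, col_b),
            "contact_prop_allatom": _pair_table_mean(
                tables.contact_prop_allatom, col_a, col_b
            ),
            "contact_prop_calpha": _pair_table_mean(
                tables.contact_prop_calpha, col_a, col_b
            ),
            "gap_frac_max": max(ctx_a.gap_frac[ca], ctx_b.gap_frac[cb]),
            "gap_frac_min": min(ctx_a.gap_frac[ca], ctx_b.gap_frac[cb]),
            "gap_share_max": max(ctx_a.gap_share[ca], ctx_b.gap_share[cb]),
            "gap_share_min": min(ctx_a.gap_share[ca], ctx_b.gap_share[cb]),
            "cooccurrence": _cooccurrence_score(col_a, col_b),
        }
        records.append(rec)
    index = pd.MultiIndex.from_tuples(pairs, names=["residue_a", "residue_b"])
    with np.errstate(invalid="ignore"):
        df = pd.DataFrame.from_records(records, index=index)
    return df[list(BASE_DESCRIPTORS)]


def aggregate_neighborhood(
    base: pd.DataFrame,
    nmap_a: NeighborhoodMap,
    nmap_b: NeighborhoodMap,
    a2o_mode: str = "union",
) -> pd.DataFrame:
    """Neighborhood aggregates of every base descriptor.

    For pair (a, b) with closed neighborhoods N(a), N(b):

    * all-to-one (``_a2o``): mean of the descriptor over
      {(a', b) : a' in N(a)} union {(a, b') : b' in N(b)} (the pair itself
      is counted once).  ``a2o_mode`` may restrict to one direction
      (``'a_to_b'`` or ``'b_to_a'``).
    * all-to-all (``_a2a``): mean over the full product N(a) x N(b).

    NaN base values are skipped in the means (NaN only if all are missing).
    """
    if a2o_mode not in ("union", "a_to_b", "b_to_a"):
        raise ValueError(f"unknown a2o_mode {a2o_mode!r}")
    cands_a = sorted({a for a, _ in base.index})
    cands_b = sorted({b for _, b in base.index})
    idx_a = {rid: i for i, rid in enumerate(cands_a)}
    idx_b = {rid: i for i, rid in enumerate(cands_b)}
    n_desc = base.shape[1]
    cube = np.full((len(cands_a), len(cands_b), n_desc), np.nan)
    for (rid_a, rid_b), row in zip(base.index, base.to_numpy()):
        cube[idx_a[rid_a], idx_b[rid_b]] = row

    neigh_a = {
        rid: sorted(idx_a[m] for m in nmap_a[rid] if m in idx_a)
        for rid in cands_a
    }
    neigh_b = {
        rid: sorted(idx_b[m] for m in nmap_b[rid] if m in idx_b)
        for rid in cands_b
    }

    a2o = np.empty((len(base), n_desc))
    a2a = np.empty((len(base), n_desc))
    with np.errstate(invalid="ignore"):
        for k, (rid_a, rid_b) in enumerate(base.index):
            ia, ib = idx_a[rid_a], idx_b[rid_b]
            na, nb = neigh_a[rid_a], neigh_b[rid_b]
            if a2o_mode == "a_to_b":
                block = cube[na, ib]
            elif a2o_mode == "b_to_a":
                block = cube[ia, nb]
            else:
                others_a = [i for i in na if i != ia]
                block = np.vstack([cube[others_a, ib], cube[ia, nb]])
            a2o[k] = np.nanmean(block, axis=0)
            a2a[k] = np.nanmean(
                cube[np.ix_(na, nb)].reshape(-1, n_desc), axis=0
            )
    out = pd.DataFrame(
        np.hstack([a2o, a2a]),
        index=base.index,
        columns=[f"{d}_a2o" for d in base.columns]
        + [f"{d}_a2a" for d in base.columns],
    )
    return out


def compute_features(
    pairs: list[tuple[ResidueId, ResidueId]],
    pa: PairedAlignment,
    col_map_a: dict[ResidueId, int],
    col_map_b: dict[ResidueId, int],
    areas_a: ResidueAreas,
    areas_b: ResidueAreas,
    nmap_a: NeighborhoodMap,
    nmap_b: NeighborhoodMap,
    tables: ScoreTables | None = None,
    a2o_mode: str = "union",
) -> pd.DataFrame:
    """Full feature matrix: base descriptors plus neighborhood aggregates."""
    base = compute_base_descriptors(
        pairs, pa, col_map_a, col_map_b, areas_a, areas_b, tables
    )
    agg = aggregate_neighborhood(base, nmap_a, nmap_b, a2o_mode)
    return pd.concat([base, agg], axis=1)


def impute_missing(
    features: pd.DataFrame, training_means: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill NaN descriptor values with (training) column means.

    Returns the imputed frame and a boolean flag frame marking imputations.
    Columns that are entirely missing fall back to 0.
    """
    means = training_means if training_means is not None else features.mean()
    means = means.fillna(0.0)
    flags = features.isna()
    return features.fillna(means), flags


@dataclass
class FeatureScaler:
    """Min/max scaling of each feature to [-1, 1] over the training set.

    Test-set values may fall outside [-1, 1] and are deliberately not
    clipped; constant training features map to 0.
    """

    minimum: np.ndarray
    maximum: np.ndarray

    @classmethod
    def fit(cls, matrix: np.ndarray | pd.DataFrame) -> "FeatureScaler":
        x = np.asarray(matrix, dtype=float)
        if x.size == 0:
            raise ValueError("cannot fit a scaler on an empty matrix")
        return cls(minimum=np.nanmin(x, axis=0), maximum=np.nanmax(x, axis=0))

    def transform(self, matrix):
        x = np.asarray(matrix, dtype=float)
        span = self.maximum - self.minimum
        safe = np.where(span == 0, 1.0, span)
        scaled = 2.0 * (x - self.minimum) / safe - 1.0
        scaled = np.where(span == 0, 0.0, scaled)
        if isinstance(matrix, pd.DataFrame):
            return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)
        return scaled

    def inverse_transform(self, matrix):
        x = np.asarray(matrix, dtype=float)
        span = self.maximum - self.minimum
        return (x + 1.0) / 2.0 * span + self.minimum
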