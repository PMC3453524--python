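"""Domain types and file plumbing for pedigree, genotype and phenotype data.

Genotype calls are stored as a compact integer code per animal x marker:

====  =============================================
code  meaning
====  =============================================
0     homozygous reference (0 copies of alt allele)
1     heterozygous
2     homozygous alternate
-1    fully missing (both allele slots unobserved)
3     one reference allele observed, one slot missing
4     one alternate allele observed, one slot missing
====  =============================================

Half-missing codes (3, 4) only arise from per-allele input such as PLINK
.ped files; the matrix-CSV dialect carries 0/1/2/NA only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1
HALF_REF = 3
HALF_ALT = 4

#: sentinel used in pedigree files for an unknown parent
UNKNOWN_PARENT = "0"


class PedigreeError(ValueError):
    pass


class GenotypeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pedigree:
    """Topologically ordered pedigree.

    ``sire``/``dam`` hold integer indices into ``ids`` (-1 for an unknown
    parent).  ``family`` labels full-sib groups: animals sharing the same
    known (sire, dam) pair share a family code; animals with any unknown
    parent get code -1.  The stored order always places parents before
    offspring.
    """

    ids: tuple[str, ...]
    sire: np.ndarray
    dam: np.ndarray
    family: np.ndarray = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "sire", np.asarray(self.sire, dtype=np.int64))
        object.__setattr__(self, "dam", np.asarray(self.dam, dtype=np.int64))
        fam = np.full(len(self.ids), -1, dtype=np.int64)
        seen: dict[tuple[int, int], int] = {}
        for i, (s, d) in enumerate(zip(self.sire, self.dam)):
            if s >= 0 and d >= 0:
                fam[i] = seen.setdefault((int(s), int(d)), len(seen))
        object.__setattr__(self, "family", fam)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_families(self) -> int:
        return int(self.family.max() + 1) if len(self.ids) else 0

    def index_of(self, animal_ids: Sequence[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.ids)}
        return np.array([lookup[a] for a in animal_ids], dtype=np.int64)

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, str | None, str | None]]
    ) -> "Pedigree":
        """Build a pedigree from (animal, sire, dam) triples.

        Parents given as ``None``, empty string or the sentinel "0" are
        unknown.  A parent that never appears as an animal is appended as a
        founder.  Records may arrive in any order; a topological order is
        established internally and a cycle raises :class:`PedigreeError`.
        """

        def norm(x):
            if x is None:
                return None
            x = str(x).strip()
            return None if x in ("", UNKNOWN_PARENT, "NA", "nan") else x

        animals: list[str] = []
        seen: set[str] = set()
        parents: dict[str, tuple[str | None, str | None]] = {}
        for a, s, d in records:
            a = str(a).strip()
            if a in seen:
                raise PedigreeError(f"duplicate animal id: {a!r}")
            seen.add(a)
            animals.append(a)
            parents[a] = (norm(s), norm(d))
        # implicit founders: parents never listed as animals
        for a in list(animals):
            for p in parents[a]:
                if p is not None and p not in seen:
                    seen.add(p)
                    animals.append(p)
                    parents[p] = (None, None)

        order = _topological_order(animals, parents)
        idx = {a: i for i, a in enumerate(order)}
        sire = np.array(
            [-1 if parents[a][0] is None else idx[parents[a][0]] for a in order]
        )
        dam = np.array(
            [-1 if parents[a][1] is None else idx[parents[a][1]] for a in order]
        )
        return cls(tuple(order), sire, dam)


def _topological_order(animals, parents):
    """Kahn's algorithm, parents first; raises listing one cycle if any."""
    children: dict[str, list[str]] = {a: [] for a in animals}
    indeg = {a: 0 for a in animals}
    for a in animals:
        for p in parents[a]:
            if p is not None:
                children[p].append(a)
                indeg[a] += 1
    queue = [a for a in animals if indeg[a] == 0]
    out = []
    while queue:
        a = queue.pop()
        out.append(a)
        for ch in children[a]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                queue.append(ch)
    if len(out) != len(animals):
        cyc = sorted(a for a in animals if indeg[a] > 0)
        raise PedigreeError(f"pedigree contains a cycle involving: {cyc[:10]}")
    return out


def read_pedigree(path: str | Path, dialect: str = "csv") -> Pedigree:
    """Read a pedigree table with columns named animal/sire/dam."""
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    try:
        a, s, d = cols["animal"], cols["sire"], cols["dam"]
    except KeyError as e:
        raise PedigreeError(f"pedigree file missing column {e}") from None
    return Pedigree.from_records(list(zip(df[a], df[s], df[d])))


def write_pedigree(ped: Pedigree, path: str | Path, dialect: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    rows = []
    for i, a in enumerate(ped.ids):
        s = ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else UNKNOWN_PARENT
        d = ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else UNKNOWN_PARENT
        rows.append((a, s, d))
    pd.DataFrame(rows, columns=["animal", "sire", "dam"]).to_csv(
        path, sep=sep, index=False
    )


# ---------------------------------------------------------------------------
# Markers and genotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerMap:
    marker_ids: tuple[str, ...]
    chrom: tuple[str, ...]
    pos: np.ndarray  # 1-based base pairs

    def __post_init__(self):
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=np.int64))
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise GenotypeError("duplicate marker ids in map")
        if np.any(self.pos < 0):
            raise GenotypeError("negative marker position")
        for c in set(self.chrom):
            p = self.pos[np.array([x == c for x in self.chrom])]
            if np.any(np.diff(p) <= 0):
                raise GenotypeError(
                    f"positions not strictly increasing on chromosome {c}"
                )

    def __len__(self) -> int:
        return len(self.marker_ids)


@dataclass(frozen=True)
class GenotypePanel:
    """Biallelic SNP calls for a set of animals plus the marker map."""

    animal_ids: tuple[str, ...]
    calls: np.ndarray  # int8, codes documented at module top
    marker_map: MarkerMap

    def __post_init__(self):
        calls = np.asarray(self.calls, dtype=np.int8)
        object.__setattr__(self, "calls", calls)
        if calls.shape != (len(self.animal_ids), len(self.marker_map)):
            raise GenotypeError(
                f"call matrix shape {calls.shape} inconsistent with "
                f"{len(self.animal_ids)} animals x {len(self.marker_map)} markers"
            )

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_map)

    def observed_allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per marker: (# observed alt alleles, # observed allele slots)."""
        c = self.calls
        alt = np.where(c == 1, 1, 0) + np.where(c == 2, 2, 0) + np.where(c == HALF_ALT, 1, 0)
        obs = (
            np.where((c >= 0) & (c <= 2), 2, 0)
            + np.where((c == HALF_REF) | (c == HALF_ALT), 1, 0)
        )
        return alt.sum(axis=0), obs.sum(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Observed alternate-allele frequency per marker (NaN if no calls)."""
        alt, obs = self.observed_allele_counts()
        with np.errstate(invalid="ignore"):
            return np.where(obs > 0, alt / np.maximum(obs, 1), np.nan)

    def has_missing(self) -> bool:
        return bool(np.any(self.calls < 0) or np.any(self.calls > 2))

    def analysis_markers(self) -> np.ndarray:
        """Boolean mask of markers with a defined allele frequency."""
        _, obs = self.observed_allele_counts()
        return obs > 0

    def subset_markers(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        mm = MarkerMap(
            tuple(self.marker_map.marker_ids[i] for i in idx),
            tuple(self.marker_map.chrom[i] for i in idx),
            self.marker_map.pos[idx],
        )
        return GenotypePanel(self.animal_ids, self.calls[:, idx], mm)

    def subset_animals(self, animal_ids: Sequence[str]) -> "GenotypePanel":
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        idx = [lookup[a] for a in animal_ids]
        return GenotypePanel(tuple(animal_ids), self.calls[idx], self.marker_map)


def read_genotypes(path: str | Path, dialect: str = "matrix-csv") -> GenotypePanel:
    """Read genotypes from matrix CSV or a PLINK-style .ped/.map pair.

    For ``plink-ped-map`` pass the path of the .ped file; the .map file is
    expected alongside it with the same stem.
    """
    if dialect == "matrix-csv":
        return _read_matrix_csv(path)
    if dialect == "plink-ped-map":
        return _read_plink(path)
    raise ValueError(f"unknown genotype dialect: {dialect!r}")


def _read_matrix_csv(path) -> GenotypePanel:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    marker_ids = tuple(df.columns[1:])
    animals = tuple(df.iloc[:, 0])
    raw = df.iloc[:, 1:].to_numpy()
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    ok = np.isin(raw, ["0", "1", "2"])
    calls[ok] = raw[ok].astype(np.int8)
    bad = ~ok & ~np.isin(raw, ["NA", "", "nan"])
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeError(
            f"invalid genotype call {raw[i, j]!r} for animal {animals[i]} "
            f"marker {marker_ids[j]}"
        )
    # matrix CSV carries no map; synthesize a single-chromosome placeholder map
    mm = MarkerMap(marker_ids, ("0",) * len(marker_ids),
                   np.arange(1, len(marker_ids) + 1))
    return GenotypePanel(animals, calls, mm)


def _read_plink(ped_path) -> GenotypePanel:
    ped_path = Path(ped_path)
    map_path = ped_path.with_suffix(".map")
    mrows = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str)
    chrom = tuple(mrows[0])
    marker_ids = tuple(mrows[1])
    pos = mrows[3].astype(np.int64).to_numpy()
    mm = MarkerMap(marker_ids, chrom, pos)
    m = len(marker_ids)

    animals = []
    allele_rows = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise GenotypeError(
                    f"ped line for animal {parts[1] if len(parts) > 1 else '?'} "
                    f"has {len(parts) - 6} allele fields, expected {2 * m}"
                )
            animals.append(parts[1])
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(len(animals), m, 2)

    calls = np.empty((len(animals), m), dtype=np.int8)
    for j in range(m):
        col = alleles[:, j, :]
        observed = sorted(set(col.ravel()) - {"0"})
        if len(observed) > 2:
            raise GenotypeError(
                f"marker {marker_ids[j]} has more than two alleles: {observed}"
            )
        ref = observed[0] if observed else "A"
        alt = observed[1] if len(observed) > 1 else None
        for i in range(len(animals)):
            a1, a2 = col[i]
            n_obs = (a1 != "0") + (a2 != "0")
            n_alt = (alt is not None) * ((a1 == alt) + (a2 == alt))
            if n_obs == 2:
                calls[i, j] = n_alt
            elif n_obs == 0:
                calls[i, j] = MISSING
            else:
                calls[i, j] = HALF_ALT if n_alt else HALF_REF
    return GenotypePanel(tuple(animals), calls, mm)


def write_genotypes(
    panel: GenotypePanel, path: str | Path, dialect: str = "matrix-csv"
) -> None:
    if dialect == "matrix-csv":
        if np.any((panel.calls == HALF_REF) | (panel.calls == HALF_ALT)):
            raise GenotypeError(
                "matrix-csv cannot represent half-missing calls; use plink-ped-map"
            )
        sym = {0: "0", 1: "1", 2: "2", MISSING: "NA"}
        rows = [
            [a] + [sym[int(c)] for c in panel.calls[i]]
            for i, a in enumerate(panel.animal_ids)
        ]
        pd.DataFrame(rows, columns=["animal", *panel.marker_map.marker_ids]).to_csv(
            path, index=False
        )
    elif dialect == "plink-ped-map":
        ped_path = Path(path)
        mm = panel.marker_map
        with open(ped_path.with_suffix(".map"), "w") as fh:
            for mid, c, p in zip(mm.marker_ids, mm.chrom, mm.pos):
                fh.write(f"{c}\t{mid}\t0\t{p}\n")
        pair = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0",
                HALF_REF: "A 0", HALF_ALT: "B 0"}
        with open(ped_path, "w") as fh:
            for i, a in enumerate(panel.animal_ids):
                g = " ".join(pair[int(c)] for c in panel.calls[i])
                fh.write(f"FAM {a} 0 0 0 -9 {g}\n")
    else:
        raise ValueError(f"unknown genotype dialect: {dialect!r}")


def impute_missing_hwe(panel: GenotypePanel, seed: int) -> GenotypePanel:
    """Fill missing calls by Hardy-Weinberg draws at observed frequencies.

    Fully missing calls are drawn from genotype probabilities
    ``{(1-p)^2, 2p(1-p), p^2}`` with ``p`` the marker's observed alternate
    allele frequency; half-missing calls draw only the unobserved allele
    from Bernoulli(p).  Uses uniform variates, so the result is reproducible
    for a given seed.
    """
    freq = panel.allele_frequency()
    needs = (panel.calls < 0) | (panel.calls > 2)
    bad = np.isnan(freq) & needs.any(axis=0)
    if bad.any():
        j = int(np.flatnonzero(bad)[0])
        raise GenotypeError(
            f"marker {panel.marker_map.marker_ids[j]} has no observed calls; "
            "remove it before imputation"
        )
    if not needs.any():
        return panel
    rng = np.random.default_rng(seed)
    calls = panel.calls.copy()
    for j in np.flatnonzero(needs.any(axis=0)):
        p = freq[j]
        rows = np.flatnonzero(needs[:, j])
        u = rng.uniform(size=rows.size)
        for r, ui in zip(rows, u):
            c = calls[r, j]
            if c == MISSING:
                # cumulative HWE probabilities: hom-ref, het, hom-alt
                q = 1.0 - p
                calls[r, j] = 0 if ui < q * q else (1 if ui < q * q + 2 * p * q else 2)
            elif c == HALF_REF:
                calls[r, j] = 1 if ui < p else 0
            elif c == HALF_ALT:
                calls[r, j] = 2 if ui < p else 1
    return replace(panel, calls=calls)


# ---------------------------------------------------------------------------
# Design encodings
# ---------------------------------------------------------------------------

ENCODING_MODES = ("dosage-centered", "per-allele", "per-allele-with-missing-allele")


@dataclass(frozen=True)
class DesignEncoding:
    """Marker design matrix in one of three codings.

    ``dosage-centered``: one column per marker, alt-allele count minus its
    column mean (zero-mean columns).  ``per-allele``: two columns per marker
    counting copies of the reference and alternate allele.
    ``per-allele-with-missing-allele``: a third column counts unobserved
    allele slots, treating "missing" as a rare pseudo-allele; every animal's
    columns for one marker then sum to 2.
    """

    mode: str
    matrix: np.ndarray  # animals x coded-columns, float64
    col_marker: np.ndarray  # column -> marker index
    marker_start: np.ndarray  # prefix: columns of marker j are [start[j], start[j+1])

    @property
    def n_markers(self) -> int:
        return len(self.marker_start) - 1

    def columns_of(self, j: int) -> slice:
        return slice(int(self.marker_start[j]), int(self.marker_start[j + 1]))


def encode_design(panel: GenotypePanel, mode: str = "dosage-centered") -> DesignEncoding:
    if mode not in ENCODING_MODES:
        raise ValueError(f"unknown encoding mode {mode!r}; expected one of {ENCODING_MODES}")
    c = panel.calls
    n, m = c.shape
    if mode != "per-allele-with-missing-allele" and panel.has_missing():
        raise GenotypeError(
            f"encoding mode {mode!r} requires a complete panel; impute first"
        )
    if mode == "dosage-centered":
        x = c.astype(np.float64)
        x -= x.mean(axis=0)
        cols_per = 1
    else:
        k = 2 if mode == "per-allele" else 3
        x = np.zeros((n, m * k))
        ref = np.select([c == 0, c == 1, c == 2, c == HALF_REF], [2, 1, 0, 1], 0)
        alt = np.select([c == 1, c == 2, c == HALF_ALT], [1, 2, 1], 0)
        x[:, 0::k] = ref
        x[:, 1::k] = alt
        if k == 3:
            x[:, 2::k] = 2 - ref - alt
        cols_per = k
    col_marker = np.repeat(np.arange(m), cols_per)
    marker_start = np.arange(m + 1) * cols_per
    return DesignEncoding(mode, x, col_marker, marker_start)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTable:
    """Per-animal trait records with design information.

    ``data`` is indexed by animal id and holds columns ``value`` (NaN =
    missing), ``cage``, ``family`` plus one column per fixed effect
    (categorical) and covariate (numeric) named in the two lists.
    """

    data: pd.DataFrame
    fixed_effects: list[str]
    covariates: list[str]

    def __post_init__(self):
        required = {"value", "cage", "family"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")

    @property
    def animal_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def observed(self) -> np.ndarray:
        return self.data["value"].notna().to_numpy()

    def mask_values(self, animal_ids: Sequence[str]) -> "PhenotypeTable":
        """Return a copy with the given animals' trait values set missing."""
        df = self.data.copy()
        df.loc[list(animal_ids), "value"] = np.nan
        return PhenotypeTable(df, list(self.fixed_effects), list(self.covariates))


def read_phenotypes(
    path: str | Path,
    fixed_effects: Sequence[str] = (),
    covariates: Sequence[str] = (),
    dialect: str = "csv",
) -> PhenotypeTable:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = pd.read_csv(path, sep=sep, dtype={"animal": str, "cage": str, "family": str})
    df = df.set_index("animal")
    return PhenotypeTable(df, list(fixed_effects), list(covariates))


def write_phenotypes(table: PhenotypeTable, path: str | Path, dialect: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    table.data.to_csv(path, sep=sep, index_label="animal")


TRANSFORMS = {
    "identity": (lambda x: x, lambda x: np.ones_like(x, dtype=bool)),
    "cube-root": (lambda x: np.cbrt(x), lambda x: x >= 0),
    "sqrt-plus-one": (lambda x: np.sqrt(x + 1.0), lambda x: x >= -1),
    "cube": (lambda x: x**3, lambda x: np.ones_like(x, dtype=bool)),
}


def transform_phenotype(
    values: Sequence[float], transform: str = "identity", scale_factor: float = 1.0
) -> np.ndarray:
    """Elementwise normalising transform followed by rescaling.

    The rescale factor keeps transformed traits on a numerically comfortable
    scale; it is a free parameter of the analysis.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    x = np.asarray(values, dtype=np.float64)
    fn, domain = TRANSFORMS[transform]
    finite = np.isfinite(x)
    ok = domain(np.where(finite, x, 0.0)) | ~finite
    if not ok.all():
        idx = int(np.flatnonzero(~ok)[0])
        raise ValueError(
            f"value {x[idx]} at index {idx} outside the domain of {transform!r}"
        )
    return np.where(finite, fn(np.where(finite, x, 0.0)) * scale_factor, np.nan)
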