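"""PLINK text PED/MAP reading and writing and the in-memory genotype model.

Genotypes are held as a samples x markers matrix of minor-allele counts
(0/1/2) with ``MISSING`` (-1) for no-calls.  Marker metadata (chromosome,
id, genetic and physical position, alleles) and sample metadata (pedigree
ids, sex, phenotype) live in pandas DataFrames indexed in matrix order.

Conventions fixed here and relied on throughout the package:

* coordinates are 1-based, intervals closed on both ends;
* chromosome labels are strings, autosomes "1".."18" sorting numerically
  and "X" after "18";
* after loading (and again after sample QC) allele1 is the minor allele,
  so every call counts copies of the minor allele;
* phenotypes use PLINK coding: 1 = control, 2 = case, -9/0 = missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

PHENO_CONTROL: int = 1
PHENO_CASE: int = 2
PHENO_MISSING: int = -9

_MARKER_COLUMNS = ["chrom", "snp", "cm", "bp", "a1", "a2"]
_SAMPLE_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]

#: sort rank for chromosome labels: numeric autosomes, then X, Y, XY, MT.
_SPECIAL_CHROM_ORDER = {"X": 100, "Y": 101, "XY": 102, "MT": 103}


class PedFormatError(ValueError):
    """Malformed PED/MAP content (column counts, allele codes)."""


def chrom_sort_key(label: str) -> int:
    """Sort rank of a chromosome label ("1".."18" numeric, "X" after "18")."""
    label = str(label)
    if label in _SPECIAL_CHROM_ORDER:
        return _SPECIAL_CHROM_ORDER[label]
    try:
        return int(label)
    except ValueError as exc:
        raise PedFormatError(f"unrecognised chromosome label {label!r}") from exc


def is_autosome(label: str) -> bool:
    return str(label) not in _SPECIAL_CHROM_ORDER


@dataclass
class GenotypeData:
    """Samples x markers minor-allele-count calls plus metadata tables.

    Attributes
    ----------
    calls : ndarray, shape (n_samples, n_markers), dtype int8
        Copies of ``a1`` (0, 1, 2) or ``MISSING``.
    markers : DataFrame with columns chrom, snp, cm, bp, a1, a2
        Sorted by (chromosome, bp); row order matches call columns.
    samples : DataFrame with columns fid, iid, father, mother, sex, phenotype
        Row order matches call rows; phenotype is PLINK-coded.
    """

    calls: np.ndarray
    markers: pd.DataFrame = field(repr=False)
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples x markers)")
        n_s, n_m = self.calls.shape
        if len(self.samples) != n_s or len(self.markers) != n_m:
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2, MISSING}")
        if not self.markers["snp"].is_unique:
            dup = self.markers["snp"][self.markers["snp"].duplicated()].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["iid"])

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers["snp"])

    def phenotypes(self) -> np.ndarray:
        return self.samples["phenotype"].to_numpy()

    def case_mask(self) -> np.ndarray:
        return self.phenotypes() == PHENO_CASE

    def control_mask(self) -> np.ndarray:
        return self.phenotypes() == PHENO_CONTROL

    def minor_allele_freqs(self) -> np.ndarray:
        """Frequency of a1 per marker over non-missing calls (NaN if all missing)."""
        calls = self.calls
        obs = calls != MISSING
        counts = np.where(obs, calls, 0).sum(axis=0)
        denom = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, counts / denom, np.nan)

    def marker_missing_rate(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    # -- subsetting ------------------------------------------------------

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeData":
        """New dataset restricted to the given positional indices (order kept)."""
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        m = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeData(
            calls=self.calls[np.ix_(s, m)].copy(),
            markers=self.markers.iloc[m].reset_index(drop=True),
            samples=self.samples.iloc[s].reset_index(drop=True),
        )

    def autosomal(self) -> "GenotypeData":
        keep = np.flatnonzero(self.markers["chrom"].map(is_autosome))
        return self.subset(marker_idx=keep)

    def set_minor_allele_first(self) -> "GenotypeData":
        """Re-orient markers so a1 is the minor allele on the current samples.

        Where a1 frequency exceeds 0.5 the alleles are swapped and calls
        flipped (2 - call); exact ties keep the lexicographically smaller
        allele as a1.
        """
        freqs = self.minor_allele_freqs()
        markers = self.markers.copy()
        calls = self.calls.copy()
        a1 = markers["a1"].to_numpy(dtype=object)
        a2 = markers["a2"].to_numpy(dtype=object)
        flip = np.zeros(self.n_markers, dtype=bool)
        for j in range(self.n_markers):
            f = freqs[j]
            if np.isnan(f):
                continue
            if f > 0.5 or (f == 0.5 and str(a2[j]) != "0" and str(a2[j]) < str(a1[j])):
                flip[j] = True
        if flip.any():
            cols = np.flatnonzero(flip)
            sub = calls[:, cols]
            sub = np.where(sub == MISSING, MISSING, 2 - sub).astype(np.int8)
            calls[:, cols] = sub
            a1[cols], a2[cols] = a2[cols].copy(), a1[cols].copy()
            markers["a1"] = a1
            markers["a2"] = a2
        return GenotypeData(calls=calls, markers=markers, samples=self.samples.copy())

    def equals(self, other: "GenotypeData") -> bool:
        return (
            np.array_equal(self.calls, other.calls)
            and self.markers[_MARKER_COLUMNS].reset_index(drop=True).equals(
                other.markers[_MARKER_COLUMNS].reset_index(drop=True)
            )
            and self.samples[_SAMPLE_COLUMNS].reset_index(drop=True).equals(
                other.samples[_SAMPLE_COLUMNS].reset_index(drop=True)
            )
        )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_VALID_ALLELES = set("ACGT012")


def read_map(map_path) -> pd.DataFrame:
    """Read a PLINK MAP file (CHR SNP CM BP, whitespace separated)."""
    markers = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "bp"],
        dtype={"chrom": str, "snp": str, "cm": float, "bp": np.int64},
        comment="#",
        float_precision="round_trip",
    )
    if markers.isna().any().any():
        raise PedFormatError(f"{map_path}: MAP requires 4 columns CHR SNP CM BP")
    if (markers["bp"] <= 0).any():
        bad = markers.loc[markers["bp"] <= 0, "snp"].iloc[0]
        raise PedFormatError(f"{map_path}: non-positive bp position at marker {bad}")
    return markers


def read_ped_map(ped_path, map_path) -> GenotypeData:
    """Parse PLINK text PED + MAP into a :class:`GenotypeData`.

    Allele pairs "0 0" become missing calls.  Per marker, a1 is set to the
    minor of the (at most two) observed alleles, ties broken so the
    lexicographically smaller allele is a1; calls count copies of a1.
    Markers are returned sorted by (chromosome, bp) regardless of MAP order;
    sample order follows the PED file.
    """
    markers = read_map(map_path)
    n_markers = len(markers)

    sample_rows = []
    allele_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            expected = 6 + 2 * n_markers
            if len(fields) != expected:
                raise PedFormatError(
                    f"{ped_path}: line {lineno} has {len(fields)} fields, "
                    f"expected {expected} (6 + 2 x {n_markers} markers)"
                )
            fid, iid, father, mother, sex, pheno = fields[:6]
            sample_rows.append(
                {
                    "fid": fid,
                    "iid": iid,
                    "father": father,
                    "mother": mother,
                    "sex": int(sex),
                    "phenotype": int(float(pheno)),
                }
            )
            alleles = fields[6:]
            for a in alleles:
                if a not in _VALID_ALLELES:
                    raise PedFormatError(
                        f"{ped_path}: line {lineno}: invalid allele code {a!r}"
                    )
            allele_rows.append(alleles)

    samples = pd.DataFrame(sample_rows, columns=_SAMPLE_COLUMNS)
    n_samples = len(samples)
    allele_arr = np.array(allele_rows, dtype="U1").reshape(n_samples, n_markers, 2) \
        if n_samples else np.empty((0, n_markers, 2), dtype="U1")

    calls = np.full((n_samples, n_markers), MISSING, dtype=np.int8)
    a1_list: list[str] = []
    a2_list: list[str] = []
    for j in range(n_markers):
        pair = allele_arr[:, j, :] if n_samples else np.empty((0, 2), dtype="U1")
        flat = pair.ravel()
        observed = flat[flat != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) > 2:
            raise PedFormatError(
                f"{ped_path}: marker {markers['snp'].iloc[j]} has "
                f"{len(uniq)} distinct alleles: {', '.join(uniq)}"
            )
        if len(uniq) == 0:
            a1, a2 = "0", "0"
        elif len(uniq) == 1:
            a1, a2 = str(uniq[0]), "0"
        elif counts[0] > counts[1]:
            a1, a2 = str(uniq[1]), str(uniq[0])
        else:
            # minor first; exact tie -> lexicographically smaller (np.unique order)
            a1, a2 = str(uniq[0]), str(uniq[1])
        a1_list.append(a1)
        a2_list.append(a2)
        if n_samples:
            nonmissing = (pair[:, 0] != "0") & (pair[:, 1] != "0")
            calls[nonmissing, j] = (pair[nonmissing] == a1).sum(axis=1)

    markers = markers.assign(a1=a1_list, a2=a2_list)
    data = GenotypeData(calls=calls, markers=markers, samples=samples)
    return sort_markers(data)


def sort_markers(data: GenotypeData) -> GenotypeData:
    """Return the dataset with markers sorted by (chromosome rank, bp)."""
    order = sorted(
        range(data.n_markers),
        key=lambda j: (
            chrom_sort_key(data.markers["chrom"].iloc[j]),
            int(data.markers["bp"].iloc[j]),
            data.markers["snp"].iloc[j],
        ),
    )
    return data.subset(marker_idx=order)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_ped_map(data: GenotypeData, ped_path, map_path) -> tuple[str, str]:
    """Write PLINK text PED/MAP; round-trips through :func:`read_ped_map`.

    Missing calls are written as "0 0"; phenotype keeps its PLINK coding.
    """
    markers = data.markers
    with open(map_path, "w") as fh:
        for row in markers.itertuples(index=False):
            cm = int(row.cm) if float(row.cm).is_integer() else row.cm
            fh.write(f"{row.chrom}\t{row.snp}\t{cm}\t{int(row.bp)}\n")

    a1 = markers["a1"].to_numpy(dtype=object)
    a2 = markers["a2"].to_numpy(dtype=object)
    with open(ped_path, "w") as fh:
        for i in range(data.n_samples):
            srow = data.samples.iloc[i]
            lead = [srow["fid"], srow["iid"], srow["father"], srow["mother"],
                    str(int(srow["sex"])), str(int(srow["phenotype"]))]
            geno: list[str] = []
            row = data.calls[i]
            for j in range(data.n_markers):
                c = row[j]
                if c == MISSING:
                    geno.extend(("0", "0"))
                elif c == 2:
                    geno.extend((a1[j], a1[j]))
                elif c == 1:
                    geno.extend((a1[j], a2[j]))
                else:
                    geno.extend((a2[j], a2[j]))
            fh.write(" ".join(lead + geno) + "\n")
    return str(ped_path), str(map_path)
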