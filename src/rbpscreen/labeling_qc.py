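"""Cy5 dye-incorporation quality control for labeled RNA probes.

Before an RNA is incubated on the array its labeling efficiency is checked
spectrophotometrically. Two figures of merit:

* **Dye density** (pmol dye per ug RNA). The dye absorbance at its
  excitation maximum (649 nm for Cy5) divided by the dye extinction
  coefficient gives the molar dye concentration (Beer-Lambert, 1 cm
  path-equivalent absorbance); multiplying by the solution volume converts
  to picomoles, and dividing by the RNA mass yields the density. The
  protocol targets ~3 pmol dye per ug RNA.

* **Base:Dye ratio** (nucleotides per attached dye). The nucleic-acid
  absorbance A260 is first corrected for the dye's own 260 nm contribution
  (A_base = A260 - A_dye * CF260, CF260 = 0.05 for Cy5), then

      Base:Dye = (A_base * e_dye) / (A_dye * e_base)

  with e_dye = 250,000 /M/cm (Cy5) and e_base = 8,250 /M/cm (average RNA
  nucleotide). The acceptance window is one dye per 700-1200 nt, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ParameterError, UnlabeledRNAError


@dataclass(frozen=True)
class LabelingConstants:
    """Spectral constants; defaults are the Cy5/RNA standard values."""

    e_dye: float = 250_000.0   # dye extinction coefficient, /M/cm
    e_base: float = 8_250.0    # average RNA nucleotide extinction, /M/cm
    cf260: float = 0.05        # dye 260 nm correction factor


@dataclass(frozen=True)
class LabelingMeasurement:
    """One labeled RNA's spectrophotometer readings.

    ``a260``/``a_dye`` are 1 cm path-equivalent absorbances; ``mass_ug`` is
    the RNA amount in micrograms and ``volume_uL`` the solution volume in
    microliters; ``length_nt`` (optional) is the transcript length.
    """

    a260: float
    a_dye: float
    mass_ug: float
    volume_uL: float
    length_nt: int | None = None

    def __post_init__(self) -> None:
        if self.a260 < 0 or self.a_dye < 0:
            raise ParameterError("absorbances must be non-negative")
        if self.mass_ug <= 0 or self.volume_uL <= 0:
            raise ParameterError("mass_ug and volume_uL must be positive")


def dye_density(m: LabelingMeasurement,
                c: LabelingConstants = LabelingConstants()) -> float:
    """Dye incorporation density in pmol dye per ug RNA.

    (a_dye / e_dye) is molar dye concentration; x volume_uL x 1e6 converts
    mol/L x uL to pmol; / mass_ug normalises per microgram of RNA. The
    solution volume is explicit because absorbance alone is a concentration
    proxy and cannot yield an amount.
    """
    return (m.a_dye / c.e_dye) * m.volume_uL * 1e6 / m.mass_ug


def base_dye_ratio(m: LabelingMeasurement,
                   c: LabelingConstants = LabelingConstants()) -> float:
    """Nucleotides per attached dye molecule.

    Raises :class:`UnlabeledRNAError` when no dye absorbance is measured and
    :class:`ParameterError` when the dye-corrected base absorbance would be
    negative (A260 < A_dye * CF260, a physically inconsistent reading).
    """
    if m.a_dye == 0:
        raise UnlabeledRNAError("A_dye = 0: no dye incorporated, ratio undefined")
    a_base = m.a260 - m.a_dye * c.cf260
    if a_base < 0:
        raise ParameterError(
            f"corrected base absorbance negative (A260={m.a260}, A_dye={m.a_dye})"
        )
    return (a_base * c.e_dye) / (m.a_dye * c.e_base)


def labeling_pass(base_dye: float, low: float = 700.0, high: float = 1200.0) -> bool:
    """True iff the base:dye ratio lies in the acceptance window (inclusive)."""
    if low >= high:
        raise ParameterError(f"invalid window: low={low} >= high={high}")
    if base_dye <= 0:
        raise ParameterError("base:dye ratio must be positive")
    return low <= base_dye <= high


def qc_batch(table: pd.DataFrame,
             c: LabelingConstants = LabelingConstants(),
             low: float = 700.0, high: float = 1200.0) -> pd.DataFrame:
    """Run labeling QC on a batch table.

    Input columns: ``id, a260, a_dye, mass_ug, volume_uL``. Returns the
    table augmented with ``dye_density_pmol_per_ug``, ``base_dye_ratio``
    and ``qc_pass`` (unlabeled RNAs get ratio NaN and fail).
    """
    out = table.copy()
    densities, ratios, passes = [], [], []
    for rec in table.itertuples(index=False):
        m = LabelingMeasurement(a260=float(rec.a260), a_dye=float(rec.a_dye),
                                mass_ug=float(rec.mass_ug),
                                volume_uL=float(rec.volume_uL))
        densities.append(dye_density(m, c))
        try:
            ratio = base_dye_ratio(m, c)
        except UnlabeledRNAError:
            ratios.append(float("nan"))
            passes.append(False)
            continue
        ratios.append(ratio)
        passes.append(labeling_pass(ratio, low, high))
    out["dye_density_pmol_per_ug"] = densities
    out["base_dye_ratio"] = ratios
    out["qc_pass"] = passes
    return out


def read_qc_tsv(path: str | Path) -> pd.DataFrame:
    """Read a labeling batch TSV (id, a260, a_dye, mass_ug, volume_uL)."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "a260", "a_dye", "mass_ug", "volume_uL"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"labeling table lacks columns: {sorted(missing)}")
    return df
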