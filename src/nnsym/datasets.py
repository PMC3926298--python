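"""Bundled contingency-table fixtures.

The package ships the NN contingency tables of the Lansing Woods forestry
survey (Clinton County, MI; 924 ft x 924 ft plot) for the black oak,
maple and white oak species (n = 1097 trees): the overall 3 x 3 NNCT and
reduced 3 x 3 Q-symmetry table, plus the restricted pairwise and
one-versus-rest sub-tables.  Raw tree coordinates are not bundled; the
tables are the published counts and support table-only analyses.

The maple-versus-rest Q-symmetry table circulates with an internally
inconsistent maple row (112 + 259 + 148 = 519, but the maple class has
514 trees).  Both that version (``..._printed``) and a corrected variant
(``..._corrected``; 148 -> 143, the unique value restoring both the row
and column margins) are provided, clearly labeled — synthetic repair of a
reference table, not survey data.
"""

from __future__ import annotations

from importlib import resources

from .tables import NNCT, QSymmetryTable, read_nnct_csv, read_qsym_csv

__all__ = ["load_nnct", "load_qsym", "available"]

_FILES = {
    "lansing": "lansing_nnct.csv",
    "lansing_qsym": "lansing_qsym.csv",
    "lansing_pair_bo_maple": "lansing_pairwise_nnct_bo_maple.csv",
    "lansing_pair_bo_wo": "lansing_pairwise_nnct_bo_wo.csv",
    "lansing_pair_maple_wo": "lansing_pairwise_nnct_maple_wo.csv",
    "lansing_pair_qsym_bo_maple": "lansing_pairwise_qsym_bo_maple.csv",
    "lansing_pair_qsym_bo_wo": "lansing_pairwise_qsym_bo_wo.csv",
    "lansing_pair_qsym_maple_wo": "lansing_pairwise_qsym_maple_wo.csv",
    "lansing_ovr_bo": "lansing_ovr_nnct_bo.csv",
    "lansing_ovr_maple": "lansing_ovr_nnct_maple.csv",
    "lansing_ovr_wo": "lansing_ovr_nnct_wo.csv",
    "lansing_ovr_qsym_bo": "lansing_ovr_qsym_bo.csv",
    "lansing_ovr_qsym_maple_printed": "lansing_ovr_qsym_maple_printed.csv",
    "lansing_ovr_qsym_maple_corrected": "lansing_ovr_qsym_maple_corrected.csv",
    "lansing_ovr_qsym_wo": "lansing_ovr_qsym_wo.csv",
}


def available() -> list:
    return sorted(_FILES)


def _path(name: str):
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; see available()")
    return resources.files("nnsym.data").joinpath(_FILES[name])


def load_nnct(name: str) -> NNCT:
    with resources.as_file(_path(name)) as p:
        return read_nnct_csv(p)


def load_qsym(name: str) -> QSymmetryTable:
    with resources.as_file(_path(name)) as p:
        return read_qsym_csv(p)
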