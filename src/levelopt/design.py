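"""Binary design matrices under the four chief-complaint specification modes.

The two baselines use a single level of the hierarchy (``complaints_only``,
``categories_only``).  The two optimized structures interpret a
specification mask over complaints:

* ``flattened`` — one mutually exclusive level: a patient with a selected
  complaint carries that complaint's indicator and is removed from its
  parent category; everyone else carries their category indicator.
* ``hierarchical`` — every patient keeps the parent-category indicator and
  additionally carries the specific-complaint indicator when selected.

All modes share the demographic/vital indicator blocks.  Matrices hold raw
one-of-K indicators; reference-level dropping (for a full-rank fit with an
intercept) happens in :meth:`DesignMatrix.for_fitting`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model import FIELD_LABELS, Cohort, SpecificationMask
from .errors import ValidationError

log = logging.getLogger(__name__)

MODES = ("flattened", "hierarchical", "complaints_only", "categories_only")


@dataclass(frozen=True)
class Block:
    """A group of indicator columns arising from one categorical predictor.

    ``exclusive`` blocks are one-of-K (exactly one indicator fires per row)
    and get a dropped reference level when fitting with an intercept;
    supplementary blocks (hierarchical-mode complaints) are never dropped.
    """

    name: str
    columns: tuple[int, ...]
    exclusive: bool
    reference: int | None  # column index into the full matrix, or None


@dataclass
class DesignMatrix:
    column_names: list[str]
    values: sp.csr_matrix
    outcome: np.ndarray
    row_ids: np.ndarray
    blocks: tuple[Block, ...]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def toarray(self) -> np.ndarray:
        return self.values.toarray()

    def for_fitting(self) -> tuple[sp.csr_matrix, list[str], np.ndarray]:
        """Drop each exclusive block's reference column (full rank + intercept)."""
        drop = {b.reference for b in self.blocks if b.exclusive and b.reference is not None}
        keep = np.array(
            [j for j in range(len(self.column_names)) if j not in drop], dtype=np.intp
        )
        names = [self.column_names[j] for j in keep]
        return self.values[:, keep], names, keep

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.toarray().astype(np.int8), columns=self.column_names
        )
        df["outcome"] = self.outcome
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _fixed_blocks(cohort: Cohort):
    """Demographic/vital indicator columns; cached per cohort (mask-free)."""
    if "fixed_blocks" in cohort._cache:
        return cohort._cache["fixed_blocks"]
    names: list[str] = []
    col_of_row: list[np.ndarray] = []
    blocks: list[Block] = []
    for field, labels in FIELD_LABELS.items():
        codes = cohort.field_codes(field)
        counts = np.bincount(codes, minlength=len(labels))
        observed = np.flatnonzero(counts)  # declared-label order
        remap = -np.ones(len(labels), dtype=np.intp)
        remap[observed] = np.arange(len(observed)) + len(names)
        ref_local = observed[np.argmax(counts[observed])]
        block = Block(
            name=field,
            columns=tuple(range(len(names), len(names) + len(observed))),
            exclusive=True,
            reference=int(remap[ref_local]),
        )
        names.extend(f"{field}={labels[i]}" for i in observed)
        col_of_row.append(remap[codes])
        blocks.append(block)
    cols = np.stack(col_of_row, axis=1)  # (rows, n_fields)
    cohort._cache["fixed_blocks"] = (names, cols, blocks)
    return cohort._cache["fixed_blocks"]


def _most_frequent(counts: np.ndarray, offset: int) -> int | None:
    if counts.size == 0 or counts.max() == 0:
        return None
    return int(offset + np.argmax(counts))


def build_design(
    cohort: Cohort,
    mask: SpecificationMask | None,
    mode: str,
) -> DesignMatrix:
    """Build the indicator design for ``cohort`` under ``mode``.

    ``mask`` is required for the flattened and hierarchical modes and
    ignored (may be None) for the two single-level baselines.  Unselected
    complaints contribute no column; a category column emptied of every
    patient (flattened mode with all its children selected, or a category
    unobserved in the cohort) is dropped.
    """
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}; expected one of {MODES}")
    hierarchy = cohort.hierarchy
    n = hierarchy.n
    if mode in ("flattened", "hierarchical"):
        if mask is None:
            raise ValidationError(f"mode {mode!r} requires a specification mask")
        if len(mask) != n:
            raise ValidationError(
                f"mask length {len(mask)} != number of complaints {n}"
            )
        selected = mask.bits.astype(bool)
    else:
        selected = None

    fixed_names, fixed_cols, fixed_blocks = _fixed_blocks(cohort)
    names = list(fixed_names)
    blocks = list(fixed_blocks)
    offset = len(names)

    comp_codes = cohort.complaint_codes
    cat_codes = cohort.category_codes
    n_cats = len(hierarchy.categories)
    rows_n = cohort.n_records
    extra_cols: list[np.ndarray] = []

    def add_category_columns(assign_codes: np.ndarray) -> np.ndarray:
        """Category columns restricted to categories with >=1 assigned row."""
        counts = np.bincount(assign_codes[assign_codes >= 0], minlength=n_cats)
        kept = np.flatnonzero(counts)
        dropped = [hierarchy.categories[i] for i in range(n_cats) if counts[i] == 0]
        if dropped:
            log.debug("dropping empty category columns: %s", dropped)
        remap = -np.ones(n_cats, dtype=np.intp)
        remap[kept] = np.arange(len(kept)) + len(names)
        names.extend(f"category={hierarchy.categories[i]}" for i in kept)
        out = -np.ones(rows_n, dtype=np.intp)
        m = assign_codes >= 0
        out[m] = remap[assign_codes[m]]
        return out

    if mode == "categories_only":
        col = add_category_columns(cat_codes)
        blocks.append(Block("category", tuple(range(offset, len(names))), True,
                            _pick_reference(col, offset, len(names))))
        extra_cols.append(col)

    elif mode == "complaints_only":
        names.extend(f"complaint={c}" for c in hierarchy.complaints)
        col = offset + comp_codes
        blocks.append(Block("complaint", tuple(range(offset, len(names))), True,
                            _pick_reference(col, offset, len(names))))
        extra_cols.append(col)

    elif mode == "flattened":
        # category indicator only for rows whose complaint is not selected
        cat_assign = np.where(selected[comp_codes], -1, cat_codes)
        cat_col = add_category_columns(cat_assign)
        sel_idx = np.flatnonzero(selected)
        comp_start = len(names)
        remap = -np.ones(n, dtype=np.intp)
        remap[sel_idx] = np.arange(len(sel_idx)) + comp_start
        names.extend(f"complaint={hierarchy.complaints[i]}" for i in sel_idx)
        comp_col = np.where(selected[comp_codes], remap[comp_codes], -1)
        combined = np.where(comp_col >= 0, comp_col, cat_col)
        blocks.append(Block("complaint_level", tuple(range(offset, len(names))), True,
                            _pick_reference(combined, offset, len(names))))
        extra_cols.append(combined)

    else:  # hierarchical
        cat_col = add_category_columns(cat_codes)
        blocks.append(Block("category", tuple(range(offset, len(names))), True,
                            _pick_reference(cat_col, offset, len(names))))
        extra_cols.append(cat_col)
        sel_idx = np.flatnonzero(selected)
        comp_start = len(names)
        remap = -np.ones(n, dtype=np.intp)
        remap[sel_idx] = np.arange(len(sel_idx)) + comp_start
        names.extend(f"complaint={hierarchy.complaints[i]}" for i in sel_idx)
        comp_col = np.where(selected[comp_codes], remap[comp_codes], -1)
        blocks.append(Block("complaint", tuple(range(comp_start, len(names))),
                            False, None))
        extra_cols.append(comp_col)

    all_cols = np.concatenate(
        [fixed_cols.ravel()] + [c[c >= 0] for c in extra_cols]
    )
    all_rows = np.concatenate(
        [np.repeat(np.arange(rows_n), fixed_cols.shape[1])]
        + [np.flatnonzero(c >= 0) for c in extra_cols]
    )
    values = sp.csr_matrix(
        (np.ones(len(all_rows)), (all_rows, all_cols)),
        shape=(rows_n, len(names)),
    )
    return DesignMatrix(
        column_names=names,
        values=values,
        outcome=cohort.outcome.astype(np.int8),
        row_ids=np.arange(rows_n),
        blocks=tuple(blocks),
    )


def _pick_reference(col_assign: np.ndarray, start: int, stop: int) -> int | None:
    """Most frequent column of an exclusive block (ties -> lowest index)."""
    if stop == start:
        return None
    counts = np.bincount(col_assign[col_assign >= 0] - start, minlength=stop - start)
    if counts.max() == 0:
        return None
    return int(start + np.argmax(counts))


def designs_equal(a: DesignMatrix, b: DesignMatrix) -> bool:
    """Bit-exact equality of column names, values, and outcomes."""
    return (
        a.column_names == b.column_names
        and a.shape == b.shape
        and (a.values != b.values).nnz == 0
        and np.array_equal(a.outcome, b.outcome)
    )
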