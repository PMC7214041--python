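"""Per-patient feature vectors of raw concept counts.

Classifiers in this package consume absolute event counts — how many times
each concept (a diagnosis, a procedure such as an emergency-room visit, a
medication, a lab) appears in a patient's record — with no scaling or
normalization. The feature list is an expert- or user-supplied ordered set
of concept codes; the column order of the matrix follows it exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
import pandas as pd

from .cohort_model import ConceptCountTable
from .errors import ConfigurationError

__all__ = ["FeatureMatrix", "build_feature_matrix", "read_concept_list"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureMatrix:
    """Patient x feature count matrix with columns ordered as supplied."""

    data: pd.DataFrame

    @property
    def patients(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def values_for(self, patients: Sequence[str]) -> np.ndarray:
        """Rows for the given patients, in the given order."""
        return self.data.loc[list(patients)].to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


def build_feature_matrix(table: ConceptCountTable,
                         concept_list: Sequence[str],
                         exclude: Sequence[str] = ()) -> FeatureMatrix:
    """Assemble the feature matrix for every patient in the table.

    Concepts in the list but absent from the table yield all-zero columns
    (with a logged warning) so a shared feature list works across cohorts.
    ``exclude`` drops concepts from the list — e.g. the target disease's
    own diagnostic code for leakage studies; by default the disease code
    stays in, which deliberately couples silver labels to one feature the
    way routinely coded data does.
    """
    concepts = [c for c in concept_list if c not in set(exclude)]
    if not concepts:
        raise ConfigurationError("concept list is empty (after exclusions)")
    if len(set(concepts)) != len(concepts):
        dupes = sorted({c for c in concepts if concepts.count(c) > 1})
        raise ConfigurationError(f"duplicate concept codes in feature list: {dupes}")
    present = [c for c in concepts if c in table.data.columns]
    missing = [c for c in concepts if c not in table.data.columns]
    if missing:
        logger.warning(
            "%d of %d requested concepts absent from the count table "
            "(zero-filled): %s", len(missing), len(concepts), missing[:10]
        )
    out = pd.DataFrame(0, index=table.data.index, columns=concepts, dtype=np.int64)
    if present:
        out[present] = table.data[present]
    return FeatureMatrix(out)


def read_concept_list(source: str | IO[str]) -> list[str]:
    """One concept code per line; blank lines and ``#`` comments ignored."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    out = []
    for line in text.splitlines():
        code = line.strip()
        if code and not code.startswith("#"):
            out.append(code)
    return out
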