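"""Document-term matrices over information-gain keywords.

Sentences are represented as rows of a sentence-by-keyword matrix in
one of three modes: binary presence, in-sentence frequency, or TF-IDF
followed by per-column z-score standardization.  IDF, column means and
standard deviations are frozen at fit time so unseen sentences are
transformed with training statistics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.io
import scipy.sparse

from .preprocess import KeywordSet

__all__ = ["DTMMode", "DTMModel", "build_dtm", "save_dtm", "load_dtm"]


class DTMMode(enum.Enum):
    BINARY = "binary"
    FREQUENCY = "frequency"
    TFIDF_Z = "tfidf_z"


@dataclass
class DTMModel:
    """Fitted document-term-matrix statistics.

    idf uses natural log of N/df (df >= 1 guaranteed: idf is only
    defined for keywords, and keywords absent from training receive
    df = 1 by construction of keyword selection on the same corpus).
    Constant TF-IDF columns z-score to 0.
    """

    keywords: list[str]
    mode: DTMMode
    idf: np.ndarray | None = None
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    _col: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._col = {w: i for i, w in enumerate(self.keywords)}

    # -- fitting ------------------------------------------------------

    def fit_transform(self, sentences: Sequence[Sequence[str]]) -> np.ndarray:
        counts = self._count(sentences)
        if self.mode is DTMMode.BINARY:
            return (counts > 0).astype(float)
        if self.mode is DTMMode.FREQUENCY:
            return counts
        n = len(sentences)
        df = np.maximum((counts > 0).sum(axis=0), 1)
        self.idf = np.log(n / df)
        x = counts * self.idf
        self.means = x.mean(axis=0)
        self.sds = x.std(axis=0)
        return self._zscore(x)

    def transform(self, sentence_words: Sequence[str]) -> np.ndarray:
        """Transform one unseen sentence with frozen training statistics."""
        counts = self._count([sentence_words])
        if self.mode is DTMMode.BINARY:
            return (counts > 0).astype(float)[0]
        if self.mode is DTMMode.FREQUENCY:
            return counts[0]
        if self.idf is None:
            raise ValueError("TFIDF_Z model must be fitted before transform")
        return self._zscore(counts * self.idf)[0]

    # -- internals ----------------------------------------------------

    def _count(self, sentences: Sequence[Sequence[str]]) -> np.ndarray:
        out = np.zeros((len(sentences), len(self.keywords)))
        for r, words in enumerate(sentences):
            for w in words:
                c = self._col.get(w.lower())
                if c is not None:
                    out[r, c] += 1
        return out

    def _zscore(self, x: np.ndarray) -> np.ndarray:
        sds = np.where(self.sds > 0, self.sds, 1.0)
        z = (x - self.means) / sds
        z[:, self.sds == 0] = 0.0
        return z


def build_dtm(
    sentences: Sequence[Sequence[str]],
    keywords: KeywordSet | Sequence[str],
    mode: DTMMode | str,
) -> tuple[DTMModel, np.ndarray]:
    """Fit a DTM over processed sentence token lists; returns (model, matrix)."""
    if isinstance(mode, str):
        try:
            mode = DTMMode(mode)
        except ValueError as exc:
            raise ValueError(f"unknown DTM mode: {mode!r}") from exc
    kws = list(keywords.keywords if isinstance(keywords, KeywordSet) else keywords)
    if not kws:
        raise ValueError("keyword set must be non-empty")
    model = DTMModel(keywords=[w.lower() for w in kws], mode=mode)
    matrix = model.fit_transform(sentences)
    return model, matrix


# ---------------------------------------------------------------------------
# Persistence: MatrixMarket matrix + column-name sidecar
# ---------------------------------------------------------------------------

def save_dtm(matrix: np.ndarray, model: DTMModel, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix) + ".mtx", scipy.sparse.csr_matrix(matrix))
    with open(str(prefix) + ".cols.tsv", "w", encoding="utf-8") as fh:
        fh.write(f"# mode\t{model.mode.value}\n")
        for i, w in enumerate(model.keywords):
            idf = "" if model.idf is None else f"\t{model.idf[i]:.10g}"
            stats = (
                ""
                if model.means is None
                else f"\t{model.means[i]:.10g}\t{model.sds[i]:.10g}"
            )
            fh.write(f"{w}{idf}{stats}\n")


def load_dtm(prefix) -> tuple[DTMModel, np.ndarray]:
    prefix = Path(prefix)
    matrix = scipy.io.mmread(str(prefix) + ".mtx").toarray()
    keywords, idf, means, sds, mode = [], [], [], [], DTMMode.BINARY
    with open(str(prefix) + ".cols.tsv", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# mode"):
                mode = DTMMode(line.rstrip().split("\t")[1])
                continue
            parts = line.rstrip("\n").split("\t")
            keywords.append(parts[0])
            if len(parts) >= 4:
                idf.append(float(parts[1]))
                means.append(float(parts[2]))
                sds.append(float(parts[3]))
    model = DTMModel(keywords=keywords, mode=mode)
    if idf:
        model.idf = np.asarray(idf)
        model.means = np.asarray(means)
        model.sds = np.asarray(sds)
    return model, matrix
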