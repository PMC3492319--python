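"""Panel genotype matrices: per-sample, per-marker allelic state calls.

Each of the panel's chromosomes is typed at some subset of the catalog's
markers; every (sample, marker) pair carries exactly one of three states:

* ``D`` — derived: the chromosome carries the post-mutation allele,
* ``A`` — ancestral: it carries the pre-mutation allele,
* ``N`` — no call: the site was not typed (or failed).

A no-call never counts as derived.  Operations that need the published
logic of "ignore untested chromosomes" expose an ``observed_only`` policy
switch; the default treats a no-call as failing any "every sample derived"
condition.

An optional companion table holds raw nucleotide calls, which are needed
when a site turns out to be triallelic and the binary D/A encoding is no
longer faithful.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO, Union

import pandas as pd

__all__ = [
    "SampleRecord",
    "DerivedSet",
    "GenotypeMatrix",
    "GenotypeError",
    "DERIVED",
    "ANCESTRAL",
    "NO_CALL",
]

DERIVED = "D"
ANCESTRAL = "A"
NO_CALL = "N"
_STATES = {DERIVED, ANCESTRAL, NO_CALL}


class GenotypeError(ValueError):
    pass


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    prior_haplogroup: Optional[str] = None
    origin: str = ""


@dataclass(frozen=True)
class DerivedSet:
    """Derived/observed sample sets for one marker.

    ``members`` are the samples called derived; ``observed`` everything
    with a call (derived or ancestral).  ``members <= observed`` always.
    """

    marker: str
    members: frozenset[str]
    observed: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members <= self.observed:
            raise GenotypeError(f"{self.marker}: members not a subset of observed")


class GenotypeMatrix:
    """Sample-by-marker state calls, backed by a pandas DataFrame."""

    def __init__(
        self,
        samples: Sequence[SampleRecord],
        markers: Sequence[str],
        states: pd.DataFrame,
        raw_alleles: Optional[pd.DataFrame] = None,
    ) -> None:
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise GenotypeError("duplicate sample ids")
        if len(set(markers)) != len(markers):
            raise GenotypeError("duplicate marker names")
        self.samples = list(samples)
        self.markers = list(markers)
        self._states = states.reindex(index=ids, columns=self.markers)
        if self._states.isna().any().any():
            raise GenotypeError("every (sample, marker) pair needs a state")
        bad = set(self._states.values.ravel()) - _STATES
        if bad:
            raise GenotypeError(f"invalid state codes: {sorted(bad)}")
        self._raw = None
        if raw_alleles is not None:
            self._raw = raw_alleles.reindex(index=ids, columns=self.markers).fillna("")
        self._by_id = {s.sample_id: s for s in self.samples}

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_calls(
        cls,
        calls: dict[str, dict[str, str]],
        samples: Optional[Sequence[SampleRecord]] = None,
        markers: Optional[Sequence[str]] = None,
        raw_alleles: Optional[dict[str, dict[str, str]]] = None,
    ) -> "GenotypeMatrix":
        """Build from ``{sample_id: {marker: state}}``; missing pairs are N."""
        if samples is None:
            samples = [SampleRecord(sid) for sid in calls]
        ids = [s.sample_id for s in samples]
        if markers is None:
            seen: dict[str, None] = {}
            for row in calls.values():
                for m in row:
                    seen.setdefault(m)
            markers = list(seen)
        states = pd.DataFrame(NO_CALL, index=ids, columns=list(markers))
        for sid, row in calls.items():
            for m, st in row.items():
                states.loc[sid, m] = st
        raw = None
        if raw_alleles is not None:
            raw = pd.DataFrame("", index=ids, columns=list(markers))
            for sid, row in raw_alleles.items():
                for m, al in row.items():
                    raw.loc[sid, m] = al
        return cls(samples, list(markers), states, raw)

    # -- basic queries -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample(self, sample_id: str) -> SampleRecord:
        try:
            return self._by_id[sample_id]
        except KeyError:
            raise GenotypeError(f"unknown sample {sample_id!r}") from None

    def state(self, sample_id: str, marker: str) -> str:
        if marker not in self._states.columns:
            raise GenotypeError(f"unknown marker {marker!r}")
        if sample_id not in self._states.index:
            raise GenotypeError(f"unknown sample {sample_id!r}")
        return self._states.at[sample_id, marker]

    def raw_allele(self, sample_id: str, marker: str) -> str:
        if self._raw is None:
            return ""
        return self._raw.at[sample_id, marker]

    @property
    def has_raw_alleles(self) -> bool:
        return self._raw is not None

    def derived_set(self, marker: str) -> DerivedSet:
        """Members and observed sets for one marker (deterministic)."""
        if marker not in self._states.columns:
            raise GenotypeError(f"unknown marker {marker!r}")
        col = self._states[marker]
        members = frozenset(col.index[col == DERIVED])
        observed = frozenset(col.index[col != NO_CALL])
        return DerivedSet(marker, members, observed)

    def shared_derived_count(
        self,
        sample_subset: Iterable[str],
        marker_subset: Iterable[str],
        policy: str = "strict",
    ) -> int:
        """Number of markers at which *every* chosen sample is derived.

        Under the default ``strict`` policy a no-call fails the "every"
        condition; under ``observed_only`` untyped samples are ignored for
        that marker (a marker with no observed sample in the subset does
        not count).
        """
        samples = list(sample_subset)
        markers = list(marker_subset)
        if not samples or not markers:
            raise GenotypeError("sample and marker subsets must be non-empty")
        unknown = [m for m in markers if m not in self._states.columns]
        if len(unknown) == len(markers):
            raise GenotypeError("no marker of the subset is in the matrix")
        if unknown:
            raise GenotypeError(f"unknown markers: {unknown}")
        if policy not in {"strict", "observed_only"}:
            raise GenotypeError(f"unknown policy {policy!r}")
        sub = self._states.loc[samples, markers]
        count = 0
        for m in markers:
            col = sub[m]
            if policy == "strict":
                ok = (col == DERIVED).all()
            else:
                obs = col[col != NO_CALL]
                ok = len(obs) > 0 and (obs == DERIVED).all()
            if ok:
                count += 1
        return count

    # -- serialization -------------------------------------------------------

    def to_tsv(self, stream: Optional[TextIO] = None) -> str:
        out = io.StringIO()
        out.write("sample_id\t" + "\t".join(self.markers) + "\n")
        for sid in self.sample_ids:
            row = self._states.loc[sid]
            out.write(sid + "\t" + "\t".join(row[m] for m in self.markers) + "\n")
        text = out.getvalue()
        if stream is not None:
            stream.write(text)
        return text

    def raw_alleles_to_tsv(self, stream: Optional[TextIO] = None) -> str:
        if self._raw is None:
            raise GenotypeError("matrix has no raw-allele table")
        out = io.StringIO()
        out.write("sample_id\t" + "\t".join(self.markers) + "\n")
        for sid in self.sample_ids:
            row = self._raw.loc[sid]
            out.write(sid + "\t" + "\t".join(row[m] for m in self.markers) + "\n")
        text = out.getvalue()
        if stream is not None:
            stream.write(text)
        return text

    @classmethod
    def from_tsv(
        cls,
        source: Union[str, TextIO],
        samples: Optional[Sequence[SampleRecord]] = None,
        raw_source: Optional[Union[str, TextIO]] = None,
    ) -> "GenotypeMatrix":
        stream = io.StringIO(source) if isinstance(source, str) else source
        df = pd.read_csv(stream, sep="\t", dtype=str).set_index("sample_id")
        raw = None
        if raw_source is not None:
            rstream = (
                io.StringIO(raw_source) if isinstance(raw_source, str) else raw_source
            )
            raw = (
                pd.read_csv(rstream, sep="\t", dtype=str)
                .set_index("sample_id")
                .fillna("")
            )
        if samples is None:
            samples = [SampleRecord(sid) for sid in df.index]
        return cls(samples, list(df.columns), df, raw)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.markers == other.markers
            and self._states.equals(other._states)
        )
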