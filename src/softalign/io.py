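"""Plain-text readers/writers for matrices, triplets, responses and labels.

All tabular files are TSV with a header row and 0-based item indices.
Floats are written with 17 significant digits so write/read round-trips
are exact to within 1e-12.  Both LF and CRLF line endings are accepted.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .triplets import PAIR_CODES, TripletResponseSet

__all__ = [
    "ParseError",
    "read_matrix",
    "write_matrix",
    "read_triplets",
    "write_triplets",
    "read_responses",
    "write_responses",
    "read_labels",
    "write_labels",
    "read_json",
    "write_json",
]

_FLOAT_FMT = "%.17g"
_PAIR_TO_CODE = {name: i for i, name in enumerate(PAIR_CODES)}


class ParseError(ValueError):
    """Malformed input file; carries the 1-based line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


def _data_lines(path) -> list[tuple[int, list[str]]]:
    text = Path(path).read_text()
    out = []
    for no, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r")
        if line.strip():
            out.append((no, line.split("\t")))
    return out


def write_matrix(path, X: np.ndarray) -> None:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    header = "\t".join(f"v{c}" for c in range(X.shape[1]))
    np.savetxt(path, X, fmt=_FLOAT_FMT, delimiter="\t", header=header, comments="")


def read_matrix(path) -> np.ndarray:
    lines = _data_lines(path)
    if not lines:
        raise ParseError(path, 1, "empty matrix file")
    rows = []
    width = len(lines[0][1])
    for no, fields in lines[1:]:
        if len(fields) != width:
            raise ParseError(path, no, f"expected {width} columns, got {len(fields)}")
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise ParseError(path, no, str(exc)) from exc
    return np.asarray(rows, dtype=float)


def write_triplets(path, triplets: np.ndarray, chosen_pair: Optional[np.ndarray] = None,
                   soft: Optional[np.ndarray] = None) -> None:
    triplets = np.asarray(triplets, dtype=np.int64)
    cols = ["i", "j", "k"]
    if chosen_pair is not None:
        cols.append("chosen_pair")
    if soft is not None:
        cols += ["p_ij", "p_ik", "p_jk"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in range(len(triplets)):
            row = [str(int(v)) for v in triplets[s]]
            if chosen_pair is not None:
                row.append(PAIR_CODES[int(chosen_pair[s])])
            if soft is not None:
                row += [_FLOAT_FMT % v for v in soft[s]]
            fh.write("\t".join(row) + "\n")


def read_triplets(path) -> TripletResponseSet:
    lines = _data_lines(path)
    if not lines:
        raise ParseError(path, 1, "empty triplet file")
    header_no, header = lines[0]
    if header[:3] != ["i", "j", "k"]:
        raise ParseError(path, header_no, "header must start with i\tj\tk")
    has_choice = "chosen_pair" in header
    has_soft = "p_ij" in header
    col = {name: idx for idx, name in enumerate(header)}
    trips, choices, soft = [], [], []
    for no, fields in lines[1:]:
        if len(fields) != len(header):
            raise ParseError(path, no, f"expected {len(header)} columns, got {len(fields)}")
        try:
            ijk = [int(fields[col[c]]) for c in ("i", "j", "k")]
        except ValueError as exc:
            raise ParseError(path, no, str(exc)) from exc
        if len(set(ijk)) != 3:
            raise ParseError(path, no, f"triplet indices must be distinct, got {ijk}")
        trips.append(ijk)
        if has_choice:
            code = fields[col["chosen_pair"]]
            if code not in _PAIR_TO_CODE:
                raise ParseError(path, no, f"chosen_pair must be one of {PAIR_CODES}, got {code!r}")
            choices.append(_PAIR_TO_CODE[code])
        if has_soft:
            try:
                soft.append([float(fields[col[c]]) for c in ("p_ij", "p_ik", "p_jk")])
            except ValueError as exc:
                raise ParseError(path, no, str(exc)) from exc
    return TripletResponseSet(
        triplets=np.asarray(trips, dtype=np.int64),
        hard_choices=np.asarray(choices, dtype=np.int64) if has_choice else None,
        soft_targets=np.asarray(soft, dtype=float) if has_soft else None,
    )


def write_responses(path, responses: TripletResponseSet) -> None:
    if responses.hard_choices is None:
        raise ValueError("responses must carry hard choices")
    pid = responses.participant_ids
    rt = responses.rt_seconds
    with open(path, "w") as fh:
        fh.write("participant_id\ti\tj\tk\tchosen_pair\trt_seconds\n")
        for s in range(len(responses)):
            fh.write(
                "\t".join(
                    [
                        str(int(pid[s]) if pid is not None else 0),
                        *(str(int(v)) for v in responses.triplets[s]),
                        PAIR_CODES[int(responses.hard_choices[s])],
                        _FLOAT_FMT % (rt[s] if rt is not None else float("nan")),
                    ]
                )
                + "\n"
            )


def read_responses(path) -> TripletResponseSet:
    lines = _data_lines(path)
    if not lines:
        raise ParseError(path, 1, "empty response file")
    header_no, header = lines[0]
    expected = ["participant_id", "i", "j", "k", "chosen_pair", "rt_seconds"]
    if header != expected:
        raise ParseError(path, header_no, f"header must be {expected}")
    pids, trips, choices, rts = [], [], [], []
    for no, fields in lines[1:]:
        if len(fields) != 6:
            raise ParseError(path, no, f"expected 6 columns, got {len(fields)}")
        try:
            pids.append(int(fields[0]))
            trips.append([int(fields[1]), int(fields[2]), int(fields[3])])
            rts.append(float(fields[5]))
        except ValueError as exc:
            raise ParseError(path, no, str(exc)) from exc
        if fields[4] not in _PAIR_TO_CODE:
            raise ParseError(path, no, f"bad chosen_pair {fields[4]!r}")
        choices.append(_PAIR_TO_CODE[fields[4]])
    return TripletResponseSet(
        triplets=np.asarray(trips, dtype=np.int64),
        hard_choices=np.asarray(choices, dtype=np.int64),
        participant_ids=np.asarray(pids, dtype=np.int64),
        rt_seconds=np.asarray(rts, dtype=float),
    )


def write_labels(path, subordinate: np.ndarray, basic: np.ndarray, superordinate: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("item_id\tsubordinate\tbasic\tsuperordinate\n")
        for idx in range(len(subordinate)):
            fh.write(f"{idx}\t{int(subordinate[idx])}\t{int(basic[idx])}\t{int(superordinate[idx])}\n")


def read_labels(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lines = _data_lines(path)
    if not lines:
        raise ParseError(path, 1, "empty label file")
    sub, bas, sup = [], [], []
    for no, fields in lines[1:]:
        if len(fields) != 4:
            raise ParseError(path, no, f"expected 4 columns, got {len(fields)}")
        try:
            sub.append(int(fields[1]))
            bas.append(int(fields[2]))
            sup.append(int(fields[3]))
        except ValueError as exc:
            raise ParseError(path, no, str(exc)) from exc
    return np.asarray(sub), np.asarray(bas), np.asarray(sup)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
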