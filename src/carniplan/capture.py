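"""Camera-trap capture histories: container plus CSV round trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io


@dataclass
class CaptureData:
    """Binary detection histories for individually identified animals.

    ``detections`` has shape (n_individuals, n_traps, n_occasions) with 0/1
    entries; every individual present has at least one detection.  ``sex``
    takes values {"F", "M", "U"}, ``age`` {"adult", "cub"}.
    """

    traps: pd.DataFrame  # trap_id, x_km, y_km
    n_occasions: int
    detections: np.ndarray
    individual_ids: list[str]
    sex: list[str]
    age: list[str]
    n_realized: int | None = None  # simulated ground truth, when known
    density_true: float | None = None

    def __post_init__(self) -> None:
        det = np.asarray(self.detections)
        if det.size and not np.isin(det, (0, 1)).all():
            raise ValueError("detections must be binary")
        if self.n_occasions < 1:
            raise ValueError("n_occasions must be >= 1")
        if det.size and det.sum(axis=(1, 2)).min() < 1:
            raise ValueError("every listed individual must have >= 1 detection")
        self.detections = det.astype(np.int8)

    @property
    def n_individuals(self) -> int:
        return self.detections.shape[0]

    @property
    def n_traps(self) -> int:
        return len(self.traps)

    def trap_coords(self) -> np.ndarray:
        return self.traps[["x_km", "y_km"]].to_numpy(dtype=float)

    def subset_adults(self) -> "CaptureData":
        """Drop cubs and unknown-age individuals (density-estimation rule)."""
        keep = [i for i, a in enumerate(self.age) if a == "adult"]
        return CaptureData(
            traps=self.traps,
            n_occasions=self.n_occasions,
            detections=self.detections[keep],
            individual_ids=[self.individual_ids[i] for i in keep],
            sex=[self.sex[i] for i in keep],
            age=[self.age[i] for i in keep],
            n_realized=self.n_realized,
            density_true=self.density_true,
        )

    def capture_frequencies(self) -> np.ndarray:
        """f_i = number of individuals detected on exactly i occasions, i=1..K.

        An occasion counts as a capture if the individual was detected at any
        trap on that occasion (non-spatial collapse).
        """
        per_occ = self.detections.max(axis=1)  # individuals x occasions
        counts = per_occ.sum(axis=1)
        f = np.zeros(self.n_occasions, dtype=int)
        for c in counts:
            f[int(c) - 1] += 1
        return f

    def has_spatial_recapture(self) -> bool:
        """True if any individual was detected at two or more traps."""
        per_trap = self.detections.max(axis=2)  # individuals x traps
        return bool(per_trap.size) and int(per_trap.sum(axis=1).max(initial=0)) >= 2

    def detections_frame(self) -> pd.DataFrame:
        rows = []
        trap_ids = self.traps["trap_id"].tolist()
        idx = np.argwhere(self.detections == 1)
        for i, j, k in idx:
            rows.append(
                {
                    "individual_id": self.individual_ids[i],
                    "sex": self.sex[i],
                    "age": self.age[i],
                    "trap_id": trap_ids[j],
                    "occasion": int(k) + 1,
                }
            )
        return pd.DataFrame(rows, columns=io.DETECTION_COLUMNS)

    def to_csv(self, traps_path: str | Path, detections_path: str | Path) -> None:
        io.write_traps(self.traps, traps_path)
        io.write_detections(self.detections_frame(), detections_path)


def capture_data_from_frames(
    traps: pd.DataFrame, detections: pd.DataFrame, n_occasions: int | None = None
) -> CaptureData:
    """Assemble a CaptureData from traps/detections tables.

    ``n_occasions`` defaults to the largest occasion index present.
    """
    if n_occasions is None:
        n_occasions = int(detections["occasion"].max()) if len(detections) else 1
    trap_ids = traps["trap_id"].tolist()
    trap_index = {t: j for j, t in enumerate(trap_ids)}
    unknown = set(detections["trap_id"]) - set(trap_ids)
    if unknown:
        raise ValueError(f"detections reference unknown trap_id(s): {sorted(map(str, unknown))}")
    if len(detections) and int(detections["occasion"].max()) > n_occasions:
        raise ValueError("occasion index exceeds n_occasions")
    ind_ids = list(dict.fromkeys(detections["individual_id"]))
    ind_index = {u: i for i, u in enumerate(ind_ids)}
    det = np.zeros((len(ind_ids), len(trap_ids), n_occasions), dtype=np.int8)
    sex = ["U"] * len(ind_ids)
    age = ["adult"] * len(ind_ids)
    for row in detections.itertuples(index=False):
        i = ind_index[row.individual_id]
        det[i, trap_index[row.trap_id], int(row.occasion) - 1] = 1
        sex[i] = str(row.sex)
        age[i] = str(row.age)
    return CaptureData(
        traps=traps.reset_index(drop=True),
        n_occasions=n_occasions,
        detections=det,
        individual_ids=[str(u) for u in ind_ids],
        sex=sex,
        age=age,
    )


def read_capture_csvs(
    traps_path: str | Path, detections_path: str | Path, n_occasions: int | None = None
) -> CaptureData:
    return capture_data_from_frames(
        io.read_traps(traps_path), io.read_detections(detections_path), n_occasions
    )
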