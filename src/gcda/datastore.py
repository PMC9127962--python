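"""Local tidy datastore for assays and kinetic measurements.

Directory layout::

    store/
      manifest.json          # signals registry + assay/sample metadata
      measurements/<id>.csv  # tidy tables: assay,sample,signal,time,value

The schema follows the study -> assay -> sample -> measurement hierarchy with
per-sample metadata (vector = design id, strain, media, supplement
concentrations) and a signal registry, so queries can filter on any of those
fields.  Values round-trip at full precision (CSV written with repr-level
floats).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

from .simulation import MEASUREMENT_COLUMNS

__all__ = ["DataStore", "StoreIntegrityError"]

_SELECTOR_KEYS = {"study", "assay", "vector", "signal", "media", "strain",
                  "supplement"}


class StoreIntegrityError(ValueError):
    pass


class DataStore:
    """Directory-backed measurement store with a JSON manifest."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.measurements_dir = self.path / "measurements"
        self.measurements_dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.path / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"signals": {}, "assays": {}}
            self.register_signal("biomass", units="OD")
            self._save_manifest()

    # -- manifest ------------------------------------------------------------

    def _save_manifest(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2) + "\n")

    def register_signal(self, signal_id: str, name: str | None = None,
                        units: str = "au") -> None:
        self.manifest.setdefault("signals", {})[signal_id] = {
            "name": name or signal_id,
            "units": units,
        }
        self._save_manifest()

    def sample_metadata(self, sample_id: str) -> dict:
        for assay in self.manifest["assays"].values():
            if sample_id in assay["samples"]:
                return assay["samples"][sample_id]
        raise KeyError(f"unknown sample {sample_id!r}")

    # -- upload --------------------------------------------------------------

    def upload_assay(
        self,
        assay_name: str,
        table: pd.DataFrame,
        sample_metadata: dict[str, dict],
        study: str = "default",
    ) -> str:
        """Persist a measurement table with its per-sample metadata.

        ``sample_metadata`` maps each sample id in the table to a dict with
        at least ``vector`` (design identifier) and optional ``strain``,
        ``media`` and ``supplements`` ({name: concentration}).  Re-uploading
        an identical (study, assay name) replaces the stored rows with a
        warning.  All non-biomass signals must be registered first.
        """
        missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
        if missing:
            raise StoreIntegrityError(f"table missing columns: {missing}")
        signals = set(table["signal"].unique())
        unregistered = signals - set(self.manifest["signals"])
        if unregistered:
            raise StoreIntegrityError(
                f"signals not registered: {sorted(unregistered)}"
            )
        for sid in table["sample"].unique():
            meta = sample_metadata.get(sid)
            if meta is None or "vector" not in meta:
                raise StoreIntegrityError(
                    f"sample {sid!r} missing metadata with a 'vector' entry"
                )

        assay_id = f"{study}__{assay_name}"
        if assay_id in self.manifest["assays"]:
            warnings.warn(
                f"assay {assay_name!r} in study {study!r} already stored; "
                "replacing"
            )
        self.manifest["assays"][assay_id] = {
            "name": assay_name,
            "study": study,
            "samples": {
                sid: {
                    "vector": meta["vector"],
                    "strain": meta.get("strain", ""),
                    "media": meta.get("media", ""),
                    "supplements": dict(meta.get("supplements", {})),
                }
                for sid, meta in sample_metadata.items()
            },
        }
        out = table[MEASUREMENT_COLUMNS].copy()
        out.to_csv(self.measurements_dir / f"{assay_id}.csv", index=False,
                   float_format="%.17g")
        self._save_manifest()
        return assay_id

    # -- query ---------------------------------------------------------------

    def query(self, **selectors) -> pd.DataFrame:
        """Conjunctive filter over the whole store.

        Selector keys: study, assay, vector, signal, media, strain,
        supplement (samples exposed to that supplement).  Empty selectors
        return everything; rows come back sorted by (sample, signal, time).
        """
        unknown = set(selectors) - _SELECTOR_KEYS
        if unknown:
            raise ValueError(f"unknown selector keys: {sorted(unknown)}")

        frames = []
        for assay_id, assay in self.manifest["assays"].items():
            if "study" in selectors and assay["study"] != selectors["study"]:
                continue
            if "assay" in selectors and assay["name"] != selectors["assay"]:
                continue
            csv = self.measurements_dir / f"{assay_id}.csv"
            if not csv.exists():
                continue
            df = pd.read_csv(csv, float_precision="round_trip")
            keep_samples = set(df["sample"].unique())
            for sid in list(keep_samples):
                meta = assay["samples"].get(sid, {})
                if "vector" in selectors and meta.get("vector") != selectors["vector"]:
                    keep_samples.discard(sid)
                elif "strain" in selectors and meta.get("strain") != selectors["strain"]:
                    keep_samples.discard(sid)
                elif "media" in selectors and meta.get("media") != selectors["media"]:
                    keep_samples.discard(sid)
                elif "supplement" in selectors and selectors["supplement"] not in meta.get("supplements", {}):
                    keep_samples.discard(sid)
            df = df[df["sample"].isin(keep_samples)]
            if "signal" in selectors:
                df = df[df["signal"] == selectors["signal"]]
            if not df.empty:
                frames.append(df)
        if not frames:
            return pd.DataFrame(columns=MEASUREMENT_COLUMNS)
        result = pd.concat(frames, ignore_index=True)
        return result.sort_values(["sample", "signal", "time"]).reset_index(drop=True)
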