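"""Per-step record of an online run."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Trace"]


@dataclass
class Trace:
    """Arrays of equal length ``T`` recorded by :func:`mblda.online.run_online`.

    ``c`` is the MBON input, ``z`` the rectified output, ``y`` the DAN label,
    ``ell`` the elapsed-time counter in effect at each step (the value used
    by that step's updates), and ``eta`` the learning rate applied.
    """

    c: np.ndarray
    z: np.ndarray
    y: np.ndarray
    ell: np.ndarray
    eta: np.ndarray

    def __post_init__(self):
        lengths = {len(self.c), len(self.z), len(self.y), len(self.ell), len(self.eta)}
        if len(lengths) != 1:
            raise ValueError(f"trace arrays have unequal lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.c)

    def running_accuracy(self, window: int = 100) -> np.ndarray:
        """Sliding-window accuracy over the previous ``min(window, t)`` steps."""
        from .evaluation import running_accuracy

        return running_accuracy(self.z, self.y, window=window)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"c": self.c, "z": self.z, "y": self.y, "ell": self.ell, "eta": self.eta}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trace":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            c=df["c"].to_numpy(float),
            z=df["z"].to_numpy(float),
            y=df["y"].to_numpy(float),
            ell=df["ell"].to_numpy(np.int64),
            eta=df["eta"].to_numpy(float),
        )
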