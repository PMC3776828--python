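"""Optional PNG figures: ethogram and top-down trajectory.

matplotlib is imported lazily so the core pipeline carries no hard plotting
dependency.
"""

from __future__ import annotations

BEHAVIOR_COLORS = {
    "directed_locomotion": "tab:green",
    "exploratory_locomotion": "tab:blue",
    "meandering": "gold",
    "standing": "black",
    "rearing": "tab:red",
}


def plot_ethogram(bouts, frame_rate: float, path, trial_id: str = "") -> None:
    """One horizontal bar per trial, coloured by behavior class over time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 1.6))
    for b in bouts:
        ax.barh(
            0,
            (b.end - b.start) / frame_rate,
            left=b.start / frame_rate,
            height=0.8,
            color=BEHAVIOR_COLORS.get(b.label, "gray"),
        )
    ax.set_yticks([])
    ax.set_xlabel("time (s)")
    ax.set_title(trial_id or "ethogram")
    handles = [
        plt.Rectangle((0, 0), 1, 1, color=c) for c in BEHAVIOR_COLORS.values()
    ]
    ax.legend(handles, BEHAVIOR_COLORS, fontsize=6, ncol=5, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectory(trace, path, arena_radius: float = 457.0, trial_id: str = "") -> None:
    """Top-down rear-CoV path coloured by CoV height."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(
        trace["rear_x_filt_mm"],
        trace["rear_y_filt_mm"],
        c=trace["rear_z_filt_mm"],
        s=2,
        cmap="jet",
    )
    circle = plt.Circle((0, 0), arena_radius, fill=False, color="gray")
    ax.add_patch(circle)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(trial_id or "rear CoV trajectory")
    fig.colorbar(sc, label="rear CoV height (mm)", shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
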