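import numpy as np
import pandas as pd
import pytest

import satbind as sb
from satbind.design import DomainSpec, LibraryDesign, backtranslate

MINI_AA = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"  # 33 residues, starts at 101


@pytest.fixture(scope="session")
def demo_design() -> LibraryDesign:
    return LibraryDesign.demo()


@pytest.fixture(scope="session")
def mini_design() -> LibraryDesign:
    """Small two-fragment design for fast end-to-end tests."""
    dom = DomainSpec("mini", 101, MINI_AA, backtranslate(MINI_AA))
    return LibraryDesign.build(
        dom, n_fragments=2, overlap=4, max_amplicon_nt=250, marker_spacing=8
    )


@pytest.fixture(scope="session")
def mini_screen(mini_design):
    """Simulated counts + ground truth for the mini design, one bait."""
    cfg = sb.EffectConfig(baits=("A",), critical_positions=(105, 110))
    effects = sb.draw_effects(mini_design, cfg, seed=3)
    counts = sb.simulate_counts(
        mini_design, effects, sb.DepthConfig(n_per_sample=3000, n_replicates=2), seed=3
    )
    return effects, counts


def make_counts(
    variant_rows: dict[tuple[int, str, str], tuple[list[int], list[int]]],
    wt_non: int = 100,
    wt_sel: int = 100,
    bait: str = "A",
    fragment: int = 1,
) -> pd.DataFrame:
    """Hand-built count table: variant -> (nonselective counts, selective
    counts) per replicate, plus marked-WT rows in every sample."""
    rows = []
    n_reps = None
    for (pos, wt, alt), (non, sel) in variant_rows.items():
        n_reps = len(non)
        for r, (cn, cs) in enumerate(zip(non, sel), start=1):
            rows.append((bait, r, "nonselective", fragment, "missense", pos, wt, alt, cn))
            rows.append((bait, r, "selective", fragment, "missense", pos, wt, alt, cs))
    for r in range(1, (n_reps or 1) + 1):
        rows.append((bait, r, "nonselective", fragment, "marked_wt", 0, "", "", wt_non))
        rows.append((bait, r, "selective", fragment, "marked_wt", 0, "", "", wt_sel))
    return pd.DataFrame(rows, columns=sb.simulate.COUNT_COLUMNS)


@pytest.fixture
def hand_counts():
    return make_counts


def make_score_table(scores: dict[tuple[int, str, str], float], bait="A",
                     status=None) -> sb.ScoreTable:
    """ScoreTable from a plain {(pos, wt, alt): score} map (all 'scored'
    unless a status map is given)."""
    rows = []
    for (pos, wt, alt), s in scores.items():
        st = (status or {}).get((pos, wt, alt), "scored")
        rows.append(("missense", pos, wt, alt, s, 0.1 if st == "scored" else np.nan,
                     st, 3, "1", 0.0))
    frame = pd.DataFrame(
        rows,
        columns=["class", "pos", "wt", "alt", "score", "se", "status",
                 "n_replicates", "fragments", "offset"],
    )
    return sb.ScoreTable(bait, frame)


@pytest.fixture
def score_table_factory():
    return make_score_table
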