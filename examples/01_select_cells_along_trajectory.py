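"""Strategic cell selection along a porto-central trajectory.

Generates a synthetic two-vein liver scene, detects and classifies the veins
from the image channels, builds the 65-degree cone ROI between them, picks
44 cells by farthest-first traversal and prints their spatial ratios.
"""

import numpy as np
from scipy import stats

from zonemap import (
    PipelineConfig,
    TissueSpec,
    generate_tissue,
    run_select,
)

channels, contours, anchors = generate_tissue(TissueSpec(seed=0))
print(f"scene: {len(contours)} segmented cells, "
      f"true central vein at {anchors['central']}, portal at {anchors['portal']}")

result = run_select(channels, contours, PipelineConfig(k=44), patient_id="P01")
traj = result["trajectory"]
table = result["table"]

print(f"detected central anchor: {traj.central.anchor}")
print(f"detected portal anchor:  {traj.portal.anchor}")
print(f"cells inside the trajectory cone: {len(traj.roi_cells)}")
print(f"cells selected for microdissection: {len(table)}")

ks = stats.kstest(table["S"], "uniform").statistic
print(f"\nspatial ratios S of the selection (0 = central vein, 1 = portal):")
print(np.round(np.sort(table['S'].to_numpy()), 3))
print(f"KS statistic vs uniform: {ks:.3f}  "
      "(small = the trajectory is covered evenly)")
print(f"\nfirst rows of the spatial table:\n{table.head(5).round(2)}")
print(f"\nLMD XML export: {result['lmd_xml'].count('<PointCount>')} shape records")
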