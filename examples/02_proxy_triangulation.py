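"""Reconstruct a 3-D point from multi-camera bounding-box centres.

Projects a known point into the 8-camera rig, perturbs one view, and
shows how the least-squares ray intersection rejects the outlier.
"""
import numpy as np

from mechwork.reconstruction import project_point, triangulate_rays
from mechwork.simulate import default_camera_rig

rig = default_camera_rig()
cams = [rig[name] for name in sorted(rig)]
truth = np.array([0.8, 4.2, 1.1])  # m, court frame

obs = {c.name: project_point(c, truth) for c in cams}
clean = triangulate_rays(cams, obs)
print(f"true point            {truth}")
print(f"8 clean views         {np.round(clean.point, 9)}  (error "
      f"{np.linalg.norm(clean.point - truth):.2e} m)")

obs["cam2"] = obs["cam2"] + np.array([50.0, 0.0])  # 50 px detector glitch
robust = triangulate_rays(cams, obs, outlier_threshold=0.1)
print(f"with a 50 px outlier  {np.round(robust.point, 9)}  (error "
      f"{np.linalg.norm(robust.point - truth):.2e} m)")
print(f"cameras kept          {robust.used}")
print("the corrupted view is dropped by the one-pass outlier rejection and")
print("the point is recovered to numerical precision from the remaining rays.")
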