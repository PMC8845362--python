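"""Grid pocket volume against an analytic cavity.

Builds hollow-shell structures enclosing exact spherical cavities, measures
their volume with the grid model at two resolutions, and reports the relative
error against 4/3 π r³.
"""

import numpy as np

from pocketmotion import build_pocket_model
from pocketmotion import synthetic as syn

for radius in (3.0, 4.0, 5.0):
    shell = syn.make_cavity_shell(radius)
    analytic = 4.0 / 3.0 * np.pi * radius**3
    for spacing in (1.0, 0.5):
        model = build_pocket_model(shell, np.zeros(3), site_radius=radius + 3, spacing=spacing)
        err = 100 * abs(model.volume - analytic) / analytic
        print(f"r={radius:.0f} Å, grid {spacing:.1f} Å: volume {model.volume:6.1f} Å³ "
              f"(analytic {analytic:6.1f}), error {err:4.1f}%, "
              f"{model.n_sub_pockets} sub-pocket(s)")
print("\nerror shrinks with the grid spacing; sub-pockets are face-connected")
print("components of cavity cells, the unit of the fusion (PF) class.")
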