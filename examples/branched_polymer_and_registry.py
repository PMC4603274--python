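"""The branched-polymer form factor and the model registry.

The registry mirrors a plug-in system: models declare named, range-checked
parameters; new models start as zero-evaluating templates; registered
models can call each other.
"""

import numpy as np

import sasmodelfit as sm
from sasmodelfit.formfactors import (REGISTRY, FormFactorModel, Parameter,
                                     make_template, register_model)

# branched polymer: excluded-volume parameter v, scaling factor c
q = np.geomspace(0.01, 2.0, 6)
P = sm.hammouda_branched_intensity(q, Rg=3.0, v=0.588, c=1.0)
print("branched polymer P(q), Rg=3, v=0.588, c=1:")
for qi, pi in zip(q, P):
    print(f"  q = {qi:8.4f}  P = {pi:.6f}")
print("P(0) = 1 by construction; the decay reflects the fractal backbone.")
print()

# a template evaluates to zero until an evaluation contract is attached
tpl = register_model(make_template("my_model", (
    Parameter("scale", "overall scale", 1.0, lo=0.0),
    Parameter("x", "dummy size", 1.0, lo=0.0),
)))
print("template intensity:", tpl.intensity(q))

# composition: a registered model may use other registered models
register_model(FormFactorModel(
    "sphere_times_two",
    parameters=(Parameter("R", "radius", 1.0, lo=0.0, open_lo=True),),
    evaluate_intensity=lambda q, R, models: 2 * models["sphere"].intensity(
        q, R=R, eta=1.0),
    uses=("sphere",),
))
print("composed model at q=0.1:",
      REGISTRY.get("sphere_times_two").intensity(0.1, R=2.0))
print()
print("registry namespaces:", REGISTRY.list())
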