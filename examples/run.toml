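# Example run configuration: impulsively started plate, SWCNT-blood nanofluid,
# fractional order 0.8, fully implicit compact scheme on standard denominators.

[physical]
phi = 0.01
gamma = 1.0
M = 0.5
K = 1.0
Pr = 25.0
Gr = 0.0
Q = 0.0
ratios = "SWCNT-blood"

[fractional]
alpha = 0.8
S = "auto"              # kernel time scale; "auto" = final time T
rl_convention = "as_printed"

[grid]
l = 5.0
N = 50
T = 0.9
Z = 90

[scheme]
omega = 0.0             # 0 = implicit, 0.5 = Crank-Nicolson, 1 = explicit
stencil_order = 4
denominator_mode = "standard"   # standard | nonstandard | nonstandard-consistent
boundary_closure = "fallback2"
drag_form = "darcy"
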