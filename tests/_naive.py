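"""Independent brute-force oracles used by the test suite."""

import numpy as np


def naive_conv2d(x, w, dilation=(1, 1)):
    """Explicit nested-loop valid correlation; x (cin, H, W), w (kh, kw, cin, cout)."""
    kh, kw, cin, cout = w.shape
    dh, dw = dilation
    H = x.shape[1] - (kh - 1) * dh
    W = x.shape[2] - (kw - 1) * dw
    out = np.zeros((cout, H, W), dtype=np.result_type(x, w))
    for o in range(cout):
        for X in range(H):
            for Y in range(W):
                acc = 0.0
                for i in range(kh):
                    for j in range(kw):
                        for c in range(cin):
                            acc += w[i, j, c, o] * x[c, X + i * dh, Y + j * dw]
                out[o, X, Y] = acc
    return out


def naive_forward(net, source, l3_dilation=2):
    """Three-layer network forward via the loop oracle (ReLU between layers)."""
    a1 = np.maximum(naive_conv2d(source, net.w1), 0.0)
    a2 = np.maximum(naive_conv2d(a1, net.w2), 0.0)
    return naive_conv2d(a2, net.w3, dilation=(1, l3_dilation))
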