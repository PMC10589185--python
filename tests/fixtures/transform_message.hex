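# TRANSFORM message wire dump
#
# 58-byte big-endian header: version=2 (u16), type name (12 bytes, NUL-padded),
# device name (20 bytes), timestamp seconds (u32) + fraction (u32, 1/2^32 units),
# body size (u64), CRC-64/ECMA-182 of the body (u64).
# 48-byte body: 12 float32 BE = rotation columns (x, y, z) then translation (mm).
# Content: device 'CTPlane', 30 deg rotation about +z, translation (10, -20, 5) mm,
# timestamp 1700000000.5 s.
#
0000  00 02 54 52 41 4e 53 46 4f 52 4d 00 00 00 43 54
0010  50 6c 61 6e 65 00 00 00 00 00 00 00 00 00 00 00
0020  00 00 65 53 f1 00 80 00 00 00 00 00 00 00 00 00
0030  00 30 1d 22 34 79 cf d9 bf 4f 3f 5d b3 d7 3f 00
0040  00 00 00 00 00 00 bf 00 00 00 3f 5d b3 d7 00 00
0050  00 00 00 00 00 00 00 00 00 00 3f 80 00 00 41 20
0060  00 00 c1 a0 00 00 40 a0 00 00
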