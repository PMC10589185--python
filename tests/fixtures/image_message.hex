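# IMAGE message wire dump
#
# Same 58-byte header (type IMAGE, device 'Reslice', timestamp 1700000001.25 s).
# 72-byte IMAGE sub-header: version=1 (u16), components (u8), scalar type (u8,
# 3=uint8), endian (u8, 1=big), coordinate (u8, 1=RAS), size i,j,k (3 x u16),
# 12 float32 BE: i/j/k axis vectors scaled by spacing then volume-centre position,
# sub-volume offset (3 x u16) and size (3 x u16, = full volume).
# Pixels: 4 x 3 x 1 uint8 ramp 0..11, i fastest on the wire.
#
0000  00 02 49 4d 41 47 45 00 00 00 00 00 00 00 52 65
0010  73 6c 69 63 65 00 00 00 00 00 00 00 00 00 00 00
0020  00 00 65 53 f1 01 40 00 00 00 00 00 00 00 00 00
0030  00 54 8f 3d 69 0b 34 87 b3 1a 00 01 01 03 01 01
0040  00 04 00 03 00 01 3f 80 00 00 00 00 00 00 00 00
0050  00 00 00 00 00 00 3f 80 00 00 00 00 00 00 00 00
0060  00 00 00 00 00 00 3f 80 00 00 3f c0 00 00 3f 80
0070  00 00 00 00 00 00 00 00 00 00 00 00 00 04 00 03
0080  00 01 00 03 06 09 01 04 07 0a 02 05 08 0b
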