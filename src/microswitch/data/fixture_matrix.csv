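,PYR_sup,PV_sup,SST_sup,VIP_sup,PYR_deep,PV_deep,SST_deep,VIP_deep
PYR_sup,0.002,-0.12,-0.0060000000000000001,-0.00020000000000000001,0.0040000000000000001,-0.0080000000000000002,-0.01,0
PV_sup,0.16,-0.17999999999999999,-0.029999999999999999,-0.00050000000000000001,0.0013230560436304382,0,-0.01,0
SST_sup,0.035000000000000003,-0.014999999999999999,0,-0.0070000000000000001,0,0,-0.0011623316248256116,0
VIP_sup,0.0080000000000000002,0,-0.014999999999999999,0,0.00086557169436519358,-0.0014709665846845501,-0.01,0
PYR_deep,0.029999999999999999,-0.0080000000000000002,-0.0026824394281533383,0,0.002,-0.12,-0.0060000000000000001,-0.0001
PV_deep,0.014999999999999999,0,-0.0014261361901185443,0,0.16,-0.26000000000000001,-0.029999999999999999,-0.00050000000000000001
SST_deep,0,-0.00040422879008791975,-0.0013883438734140165,0,0.035000000000000003,-0.014999999999999999,0,-0.0070000000000000001
VIP_deep,0,-0.001688157361157184,0,0,0.0080000000000000002,0,-0.014999999999999999,0
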