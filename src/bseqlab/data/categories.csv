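raw_label,berlin_label,jhuang_label
Travel.m.,Distance_traveled,Distance_traveled
ComeDown,ComeDown,Rear
RearUp,Rearup,Rear
Turn,Walk,Walk
Stretch,Stretch,Rear
HangCudl,Hang,Hang
HangVert,Hang,Hang
CDfromPR,ComeDown,Rear
CDtoPR,Rearup,Rear
RUfromPR,Rearup,Rear
RUtoPR,Rearup,Rear
LandVert,Hang,Rear
WalkLeft,Walk,Walk
WalkRght,Walk,Walk
Stationa,Immobile,Rest
Drnk.S1.,Drink,Drink
Eat.Z1.,Eat,Eat
Jump,Jump,Unknown_behavior
Unknown,Unknown,Unknown_behavior
HVfromRU,Hang,Hang
HVfromHC,Hang,Hang
ReptJump,Jump,Unknown_behavior
Circle,Walk,Walk
Dig,Digforage,Unknown_behavior
Forage,Digforage,Unknown_behavior
Pause,Immobile,Micro_move
Urinate,Unknown,Unknown_behavior
Groom,Groom,Groom
Sleep,Immobile,Rest
Twitch,Twitch,Micro_move
Arousal,,
Awaken,Awaken,Micro_move
Chew,Chew,Eat
Sniff,Sniffing,Micro_move
RemainRU,Rearup,Rear
RemainPR,Rearup,Rear
RemainHV,Hang,Hang
RemainHC,Hang,Hang
RemainLw,RemainLow,Micro_move
WalkSlow,Walk,Walk
No.Data,,
Drnk.S2.,Drink,Drink
Drnk.S3.,Drink,Drink
Eat.Z2.,Eat,Eat
Eat.Z3.,Eat,Eat
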