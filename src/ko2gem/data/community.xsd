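<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">
  <xs:element name="community">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="member" maxOccurs="unbounded">
          <xs:complexType>
            <xs:attribute name="id" type="xs:string" use="required"/>
            <xs:attribute name="model" type="xs:string"/>
            <xs:attribute name="abundance" type="xs:double" default="1.0"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="shared" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:attribute name="metabolite" type="xs:string" use="required"/>
            <xs:attribute name="total" type="xs:double" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="link" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:attribute name="metabolite" type="xs:string" use="required"/>
            <xs:attribute name="from" type="xs:string" use="required"/>
            <xs:attribute name="to" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="id" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
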